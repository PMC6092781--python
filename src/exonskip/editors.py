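"""Base-editor definitions: PAM patterns and per-position editing efficiency.

A C>T base editor (Cas9 nickase fused to a cytidine deaminase) converts
cytidines within a PAM-distal window of the protospacer.  Positions are
numbered 1-based from the PAM-distal (5') end, so for a 20-nt SpCas9
protospacer position 20 is adjacent to the PAM and a target cytidine at
position p sits ``protospacer_length - p + 1`` bp from the PAM.

Default editor definitions ship as a JSON config; their efficiency
profiles are approximate values digitized from published editing-window
figures and are data, not code — replace them via ``load_editors``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class PamMatcher:
    """Compiled IUPAC PAM pattern.

    An ``N`` in the *genome* never matches anything (unknown base), while an
    ``N`` in the pattern matches any of ACGT.
    """

    pattern: str
    allowed: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, kmer: str) -> bool:
        if len(kmer) != len(self.allowed):
            return False
        return all(base in ok for base, ok in zip(kmer, self.allowed))


def compile_pam(pattern: str) -> PamMatcher:
    """Compile an IUPAC pattern (e.g. NGG, NNNRRT) into a matcher."""
    pattern = pattern.upper()
    try:
        allowed = tuple(IUPAC[c] for c in pattern)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in PAM pattern {pattern!r}") from None
    return PamMatcher(pattern, allowed)


class EfficiencyProfile:
    """Per-position editing efficiency, 1-based PAM-distal numbering.

    Positions absent from the map edit with efficiency 0.
    """

    def __init__(self, efficiencies: Mapping[int, float]):
        for pos, val in efficiencies.items():
            if pos < 1:
                raise ValueError(f"profile position {pos} < 1")
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"efficiency {val} at position {pos} outside [0,1]")
        self._eff = {int(p): float(v) for p, v in efficiencies.items() if v > 0}

    def __getitem__(self, position: int) -> float:
        return self._eff.get(position, 0.0)

    @property
    def positions(self) -> list[int]:
        """Positions with non-zero efficiency, ascending."""
        return sorted(self._eff)

    @property
    def max_efficiency(self) -> float:
        return max(self._eff.values(), default=0.0)

    def __eq__(self, other) -> bool:
        return isinstance(other, EfficiencyProfile) and self._eff == other._eff

    def __repr__(self) -> str:
        return f"EfficiencyProfile({self._eff!r})"


@dataclass(frozen=True)
class BaseEditor:
    """A named C>T base editor."""

    name: str
    pam: str
    protospacer_length: int
    profile: EfficiencyProfile
    secondary_pams: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.protospacer_length < 15:
            raise ValueError("protospacer_length must be >= 15")
        compile_pam(self.pam)  # validates
        for p in self.secondary_pams:
            compile_pam(p)

    @property
    def pam_matcher(self) -> PamMatcher:
        return compile_pam(self.pam)

    def scan_pam_matchers(self, include_secondary: bool = True) -> list[PamMatcher]:
        """PAM patterns used for off-target scanning (primary + secondary)."""
        pams = [self.pam] + (list(self.secondary_pams) if include_secondary else [])
        return [compile_pam(p) for p in pams]

    def c_to_pam_distance(self, position: int) -> int:
        """Distance in bp from a protospacer position to the PAM."""
        return self.protospacer_length - position + 1


def build_efficiency_profile(
    measurements: Mapping[int, Sequence[float]],
    alpha: float = 0.1,
) -> EfficiencyProfile:
    """Conservative profile from replicate efficiency measurements.

    A position gets the replicate mean only when a one-sided one-sample
    t-test rejects "mean efficiency <= 0" at p < ``alpha`` (default 0.1);
    otherwise it is 0, suppressing false-positive windows.  Positions with a
    single replicate cannot be tested and report 0 (logged).
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    out: dict[int, float] = {}
    for pos, reps in measurements.items():
        reps = np.asarray(list(reps), dtype=float)
        if reps.size == 0:
            raise ValueError(f"position {pos} has no replicates")
        if reps.size == 1:
            logger.info("position %d has a single replicate; t-test undefined, reporting 0", pos)
            out[pos] = 0.0
            continue
        if np.allclose(reps, reps[0]):
            # zero variance: mean > 0 is either trivially rejected or not testable;
            # treat a strictly positive constant as significant, else 0
            out[pos] = float(reps.mean()) if reps[0] > 0 else 0.0
            continue
        res = stats.ttest_1samp(reps, 0.0, alternative="greater")
        mean = float(reps.mean())
        out[pos] = mean if (res.pvalue < alpha and mean > 0) else 0.0
    return EfficiencyProfile({p: v for p, v in out.items() if v > 0})


def _editor_from_dict(d: dict) -> BaseEditor:
    return BaseEditor(
        name=d["name"],
        pam=d["pam"],
        protospacer_length=int(d["protospacer_length"]),
        profile=EfficiencyProfile({int(k): float(v) for k, v in d["profile"].items()}),
        secondary_pams=tuple(d.get("secondary_pams", [])),
    )


def load_editors(path=None) -> dict[str, BaseEditor]:
    """Load editor definitions from a JSON config (default: shipped table)."""
    if path is None:
        text = resources.files("exonskip.data").joinpath("editors.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = json.loads(text)
    editors = [_editor_from_dict(d) for d in data["editors"]]
    return {e.name: e for e in editors}


def default_editors() -> dict[str, BaseEditor]:
    """The four shipped editors keyed by name."""
    return load_editors()
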