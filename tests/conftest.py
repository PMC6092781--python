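import pytest

from exonskip.editors import EfficiencyProfile, BaseEditor, default_editors
from exonskip.genome import Genome
from exonskip.simulate import FixtureSpec, PlantedGuide, PlantedOfftarget, make_toy_genome


@pytest.fixture(scope="session")
def editors():
    return default_editors()


@pytest.fixture(scope="session")
def be3(editors):
    return editors["SpCas9-BE3"]


@pytest.fixture
def tiny_editor():
    """Short-protospacer editor for hand-checkable fixtures."""
    return BaseEditor(
        name="tiny",
        pam="NGG",
        protospacer_length=15,
        profile=EfficiencyProfile({5: 0.4, 6: 0.5, 7: 0.3}),
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """Two-transcript toy genome (one strand each) with one planted guide per
    transcript and planted off-target sites at 1 and 2 mismatches."""
    spec = FixtureSpec(
        seed=11,
        n_transcripts=2,
        planted_guides=(
            PlantedGuide(0, 1, "SpCas9-BE3", 6),
            PlantedGuide(1, 1, "SpCas9-BE3", 7),
        ),
        planted_offtargets=(
            PlantedOfftarget(0, 1, "+"),
            PlantedOfftarget(0, 2, "-"),
        ),
    )
    return make_toy_genome(spec)


def make_genome(**contigs) -> Genome:
    return Genome({k: v.upper() for k, v in contigs.items()})
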