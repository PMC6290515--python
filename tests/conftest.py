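import pytest

from flexscan.fixtures import DisorderBlock, FixtureSpec, make_family, write_family


@pytest.fixture(scope="session")
def family_spec():
    """A small homolog family: 30% + 30% disordered termini, ordered core."""
    return FixtureSpec(
        seed=11, family_size=5, ancestor_length=240,
        substitution_rate=0.05, indel_rate=0.01,
        disorder_blocks=(
            DisorderBlock(1, 72, "disordered"),
            DisorderBlock(73, 168, "ordered"),
            DisorderBlock(169, 240, "disordered"),
        ),
    )


@pytest.fixture(scope="session")
def family(family_spec):
    return make_family(family_spec)


@pytest.fixture()
def family_dir(tmp_path, family_spec):
    """The same family written to disk (FASTA + score files + truth)."""
    write_family(family_spec, tmp_path / "fam")
    return tmp_path / "fam"
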