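import pytest

from iontally.modifications import (
    ModRegistry,
    build_aa_lookup,
    compile_mod_sets,
    parse_mod_spec,
)
from iontally.simulate import random_protein_fasta


@pytest.fixture(scope="session")
def registry():
    return ModRegistry()


@pytest.fixture(scope="session")
def spec(registry):
    """Parse a modification specification string against the registry."""

    def _parse(text):
        return parse_mod_spec(text, registry)

    return _parse


@pytest.fixture(scope="session")
def worked_example_sets(spec):
    """The TMT10plex global-search specification: fixed Carbamidomethyl (C),
    TMT10plex (N-term), TMT10plex (K); variable Acetyl (Protein N-term),
    Gln->pyro-Glu (N-term = Q), Oxidation (M), Deamidated (N)."""
    fixed = [
        spec("Carbamidomethyl (C)"),
        spec("TMT10plex (N-term)"),
        spec("TMT10plex (K)"),
    ]
    variable = [
        spec("Acetyl (Protein N-term)"),
        spec("Gln->pyro-Glu (N-term = Q)"),
        spec("Oxidation (M)"),
        spec("Deamidated (N)"),
    ]
    return compile_mod_sets(fixed, variable)


@pytest.fixture(scope="session")
def ox_modsets(spec):
    """Fixed Carbamidomethyl (C) + variable Oxidation (M): two sets."""
    return compile_mod_sets(
        [spec("Carbamidomethyl (C)")], [spec("Oxidation (M)")]
    )


@pytest.fixture(scope="session")
def ox_lookups(ox_modsets):
    return {m.set_index: build_aa_lookup(m) for m in ox_modsets}


@pytest.fixture(scope="session")
def plain_lookup():
    """Lookup with no modifications at all."""
    [ms] = compile_mod_sets([], [])
    return build_aa_lookup(ms)


@pytest.fixture(scope="session")
def tiny_fasta(tmp_path_factory):
    """Five random synthetic proteins written to disk once per session."""
    path = tmp_path_factory.mktemp("db") / "target.fasta"
    records = random_protein_fasta(path, n_proteins=5, seed=7)
    return path, records
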