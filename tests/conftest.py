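import pytest
from hypothesis import settings

import rincluster as rc
from rincluster import fixtures as fx

settings.register_profile("ci", max_examples=100, derandomize=True, deadline=None)
settings.load_profile("ci")

LADDER = (3.2, 3.8, 12.0)


@pytest.fixture(scope="session")
def site_spec():
    return fx.SiteSpec(
        ligand="disaccharide",
        shell=[fx.ShellResidue("GLU", LADDER[0], (0, 1, 0), 212),
               fx.ShellResidue("ASP", LADDER[1], (0, -1, 0), 214),
               fx.ShellResidue("HIS", LADDER[2], (0, 0, 1), 228)],
        waters=[(2.8, (1, 0, 0))],
        rng_seed=7)


@pytest.fixture(scope="session")
def site_pdb(site_spec):
    return fx.make_synthetic_site(site_spec)


@pytest.fixture(scope="session")
def protonated_site(site_pdb):
    return rc.add_hydrogens(rc.read_pdb(site_pdb))


@pytest.fixture(scope="session")
def tripeptide():
    return fx.build_peptide(["GLY", "ALA", "SER"])
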