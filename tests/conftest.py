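import pytest

from alphasheet.design import ALPHA_SHEET, BETA_SHEET, TemplateSpec, make_ideal_template
from alphasheet.fixtures import JitterSpec, generate_ensemble
from alphasheet.geometry import DihedralTriple, build_backbone


@pytest.fixture(scope="session")
def alpha_template():
    return make_ideal_template(TemplateSpec(conformation=ALPHA_SHEET))


@pytest.fixture(scope="session")
def beta_template():
    return make_ideal_template(TemplateSpec(conformation=BETA_SHEET))


@pytest.fixture(scope="session")
def alpha_ensemble_small():
    """20-frame, σ=8° jittered ensemble around the default α template."""
    return generate_ensemble(JitterSpec(template=TemplateSpec(), sigma=8.0,
                                        n_frames=20, seed=11))


def random_dihedrals(rng, n, omega_trans=True):
    """Random but valid per-residue dihedrals for an n-residue linear chain."""
    out = []
    for i in range(n):
        out.append(
            DihedralTriple(
                phi=None if i == 0 else float(rng.uniform(-179.0, 180.0)),
                psi=None if i == n - 1 else float(rng.uniform(-179.0, 180.0)),
                omega=None if i == n - 1 else (
                    180.0 if omega_trans else float(rng.uniform(-179.0, 180.0))
                ),
            )
        )
    return out


def random_chain(rng, n=8, seq=None):
    if seq is None:
        letters = list("ACDEFHIKLMNQRSTVWY")
        seq = "".join(
            rng.choice(letters).lower() if rng.random() < 0.3 else rng.choice(letters)
            for _ in range(n)
        )
    return build_backbone(seq, random_dihedrals(rng, n))
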