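import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrpipe import HarmonizedInstrument, fixture_small, harmonize, retained

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_instruments(
    n: int,
    seed: int,
    slope: float = 0.4,
    intercept: float = 0.0,
    noise: float = 0.01,
) -> list[HarmonizedInstrument]:
    """Random harmonized instruments around by = intercept + slope * bx."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.02, 0.08, n) * rng.choice([-1.0, 1.0], n)
    sy = rng.uniform(0.005, 0.03, n)
    sx = rng.uniform(0.001, 0.004, n)
    by = intercept * np.sign(bx) + slope * bx + rng.normal(0.0, noise, n)
    return [
        HarmonizedInstrument(
            variant_id=f"rs{i}",
            effect_allele="A",
            other_allele="G",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
            eaf=0.3,
            action_taken="kept",
            pval_exp=1e-10,
            n_exp=300_000,
        )
        for i in range(n)
    ]


def write_tables_from_mvmr_sim(sim, directory):
    """Write one TSV per simulated exposure plus the outcome table.

    Returns (exposure_paths, outcome_path). All variants share an A/G coding
    at eaf 0.3, so harmonization keeps everything and the tables exercise
    selection and estimation rather than allele logic.
    """
    from scipy import stats

    directory.mkdir(parents=True, exist_ok=True)
    header = "SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
    exposure_paths = []
    for e, name in enumerate(sim.exposure_names):
        lines = [header]
        for j, vid in enumerate(sim.variant_ids):
            beta = float(sim.beta_exp_hat[j, e])
            se = float(sim.se_exp[j, e])
            pval = float(stats.chi2.sf((beta / se) ** 2, 1))
            lines.append(f"{vid}\tA\tG\t0.3\t{beta!r}\t{se!r}\t{pval!r}\t300000\n")
        path = directory / f"{name}.tsv"
        path.write_text("".join(lines))
        exposure_paths.append(path)
    lines = [header]
    for j, vid in enumerate(sim.variant_ids):
        beta = float(sim.beta_out_hat[j])
        se = float(sim.se_out[j])
        pval = float(stats.chi2.sf((beta / se) ** 2, 1))
        lines.append(f"{vid}\tA\tG\t0.3\t{beta!r}\t{se!r}\t{pval!r}\t280000\n")
    outcome_path = directory / "outcome.tsv"
    outcome_path.write_text("".join(lines))
    return exposure_paths, outcome_path


@pytest.fixture(scope="session")
def toy_pair():
    return fixture_small()


@pytest.fixture(scope="session")
def toy_instruments(toy_pair):
    exposure, outcome, _ld, _truth = toy_pair
    return retained(harmonize(exposure, outcome))
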