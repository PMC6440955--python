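import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from helixdx.peptides import A26_55_WT, A28_55_WT  # noqa: E402
from helixdx.synthetic_data import (  # noqa: E402
    ExchangeTruth,
    TrajectoryTruth,
    gen_exchange_dataset,
    gen_helix_trajectory,
    step_delta_g_profile,
)


@pytest.fixture(scope="session")
def wt_peptide():
    return A26_55_WT


@pytest.fixture(scope="session")
def straight_open_traj():
    """Straight helix, planted per-residue open probabilities, no bend."""
    truth = TrajectoryTruth(
        n_frames=1000, bend_mean_deg=0.0, bend_sd_deg=0.0, rho=0.0, seed=11
    )
    return gen_helix_trajectory(truth)


@pytest.fixture(scope="session")
def rigid_helix_traj():
    """Near-rigid straight helix (no opening, tiny jitter)."""
    truth = TrajectoryTruth(
        n_frames=200, bend_mean_deg=0.0, bend_sd_deg=0.0, rho=0.0,
        open_probabilities={}, jitter_nm=0.0005, seed=12,
    )
    return gen_helix_trajectory(truth)


@pytest.fixture(scope="session")
def kinked_traj_5000():
    """5000-frame helix with a planted 30 degree kink at the G37/G38 hinge."""
    truth = TrajectoryTruth(
        n_frames=5000, bend_mean_deg=30.0, bend_sd_deg=1.0, rho=0.5,
        open_probabilities={}, jitter_nm=0.002, seed=13,
    )
    return gen_helix_trajectory(truth)


@pytest.fixture(scope="session")
def kinked_traj_swivelled():
    """Same kink rotated by +90 degrees about the helix axis."""
    truth = TrajectoryTruth(
        n_frames=2000, bend_mean_deg=30.0, bend_sd_deg=1.0, rho=0.5,
        bend_direction_deg=90.0, open_probabilities={}, jitter_nm=0.002,
        seed=13,
    )
    return gen_helix_trajectory(truth)


@pytest.fixture(scope="session")
def exchange_dataset(tmp_path_factory):
    """Assay-design exchange dataset written to and re-read from disk."""
    from helixdx import io as hio

    out = tmp_path_factory.mktemp("exchange")
    pep = A28_55_WT
    truth = ExchangeTruth(delta_g=step_delta_g_profile(pep), seed=7)
    gen_exchange_dataset(truth, pep, out_dir=out)
    import json

    fragments = hio.read_fragments(out / "fragments.csv")
    overall = hio.read_overall_curve(out / "overall.csv")
    record = json.loads((out / "truth.json").read_text())
    return pep, truth, fragments, overall, record


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
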