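import numpy as np
import pytest

from richscape import simulate as sim


@pytest.fixture(scope="session")
def landscape():
    """100x100 four-group synthetic landscape with default structure."""
    cfg = sim.LandscapeConfig(seed=3)
    env, truth = sim.gen_env_stack(cfg)
    return env, truth


@pytest.fixture(scope="session")
def three_cov_env():
    """Small stack restricted to three covariates, for suitability tests."""
    cfg = sim.LandscapeConfig(
        shape=(100, 100),
        group_sizes={"climate": 1, "soil": 1, "terrain": 2, "anthropogenic": 1},
        corr_range=5.0, seed=3)
    env, _ = sim.gen_env_stack(cfg)
    return env.subset(env.names[:3])


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run, shared across tests."""
    from richscape import pipeline

    out = tmp_path_factory.mktemp("pipeline") / "run"
    pipeline.run_pipeline({"outdir": str(out), "seed": 1})
    return out


def brute_force_jenks(values, k):
    """Exhaustive optimal contiguous k-partition SSW (oracle, n <= ~14)."""
    import itertools

    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        ssw = sum(float(np.sum((x[lo:hi] - x[lo:hi].mean()) ** 2))
                  for lo, hi in zip(bounds[:-1], bounds[1:]))
        best = min(best, ssw)
    return best


def anova_q_oracle(y, labels):
    """Two-pass ANOVA decomposition of the variance-explained share."""
    y = np.asarray(y, dtype=float)
    ssw = sum(float(np.sum((y[labels == h] - y[labels == h].mean()) ** 2))
              for h in np.unique(labels))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ssw / sst
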