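"""Shared fixtures.

Heavy lattice objects (fold repertoire, validation bench) are session-scoped:
the repertoire enumeration takes ~30 s and the scaled-down validation bench a
few minutes, and several acceptance checks share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from pottsfocus.alignment import Alignment, encode_sequence


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_alignment(strings: list[str], wt: str, ids: list[str] | None = None) -> Alignment:
    seqs = np.stack([encode_sequence(s) for s in strings])
    return Alignment(
        ids=ids or [f"s{k}" for k in range(len(strings))],
        seqs=seqs,
        wt=encode_sequence(wt),
    )


@pytest.fixture()
def toy_alignment() -> Alignment:
    # 4 ungapped sequences, wt = first
    strings = ["ACDEF", "ACDEY", "ACKEY", "WCKEY"]
    return make_alignment(strings, "ACDEF")


@pytest.fixture(scope="session")
def repertoire():
    from pottsfocus.lattice import enumerate_folds

    return enumerate_folds(dedup_reversal=False)


@pytest.fixture(scope="session")
def small_world():
    """Cheap lattice world for sampler and wild-type tests."""
    from pottsfocus.lattice import make_world

    return make_world(n_competitors=500, seed=2)


@pytest.fixture(scope="session")
def small_wt(small_world):
    from pottsfocus.lattice import select_wildtype

    return select_wildtype(small_world, seed=2)


@pytest.fixture(scope="session")
def bench_result():
    """The scaled-down validation bench shared by the acceptance checks."""
    from pottsfocus.bench import run_validation_bench

    return run_validation_bench(seed=1)


@pytest.fixture(scope="session")
def structural_analysis(bench_result):
    """Dense Potts fit on a large unbiased lattice alignment.

    The alignment size is reduced from the production default to keep the
    suite within its time budget; the structural/non-structural variance
    contrast is robust at this scale.
    """
    from pottsfocus.lattice import SamplerConfig, metropolis_sample
    from pottsfocus.lattice import structural_coupling_analysis

    world = bench_result.world
    wt = bench_result.metrics["wt"]
    cfg = SamplerConfig(gamma=0.0, n_samples=6000, n_chains=12, seed=77)
    big = metropolis_sample(world, wt, cfg)
    return structural_coupling_analysis(big, world, k_range=np.arange(0, 41, 2))


@pytest.fixture(scope="session")
def focus_bundle(bench_result):
    """Focusing sweep of the independent model on the pooled lattice MSA,
    plus the bias factor fitted from the bench's K = 0 records."""
    from pottsfocus.biasvar import ModelSpec, fit_bias_factor, focus_curve
    from pottsfocus.prediction import scan_from_truth

    pool = bench_result.metrics["pool"]
    truth = bench_result.truth
    scan = scan_from_truth(truth.fitness_effects, truth.wt, mask=truth.mask)
    spec = ModelSpec(k=0, use_weights=False)
    curve = focus_curve(pool, scan, spec, d_cut_values=range(4, 28))
    j0 = fit_bias_factor([r for r in bench_result.records if r.k == 0]).j0
    return curve, j0
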