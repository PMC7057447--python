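"""Shared fixtures and oracle helpers for the methylstates test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylstates import HmmParams, MethylationProfile, Platform, tnorm_logpdf


def make_profile(
    pos,
    beta,
    chrom="chr1",
    platform=Platform.HM450K,
    detection_p=None,
    island=None,
):
    """Small hand-specified profile; pos/beta aligned sequences."""
    n = len(pos)
    chroms = [chrom] * n if isinstance(chrom, str) else list(chrom)
    df = pd.DataFrame(
        {
            "probe_id": [f"cg{i:06d}" for i in range(n)],
            "chrom": chroms,
            "pos": list(pos),
            "beta": list(beta),
        }
    )
    if detection_p is not None:
        df["detection_p"] = list(detection_p)
    if island is not None:
        df["island_member"] = list(island)
    return MethylationProfile(df, platform=platform)


def random_params(rng: np.random.Generator) -> HmmParams:
    """Random valid two-state parameters for decoder stress tests."""
    pi = rng.dirichlet([1.0, 1.0])
    A = np.vstack([rng.dirichlet([1.0, 1.0]), rng.dirichlet([1.0, 1.0])])
    means = np.sort(rng.uniform(0.05, 0.95, size=2))
    sds = rng.uniform(0.03, 0.3, size=2)
    return HmmParams(pi=pi, A=A, means=means, sds=sds)


def brute_force_paths(obs: np.ndarray, params: HmmParams):
    """Score every 2^k state path under the joint model (enumeration oracle)."""
    k = obs.size
    paths = (
        np.array(np.meshgrid(*([[0, 1]] * k), indexing="ij")).reshape(k, -1).T
    )
    logB = np.column_stack(
        [tnorm_logpdf(obs, params.means[s], params.sds[s]) for s in (0, 1)]
    )
    with np.errstate(divide="ignore"):
        lpi = np.log(params.pi)
        lA = np.log(params.A)
    scores = lpi[paths[:, 0]] + logB[0, paths[:, 0]]
    for t in range(1, k):
        scores = scores + lA[paths[:, t - 1], paths[:, t]] + logB[t, paths[:, t]]
    return paths, scores


def brute_force_viterbi(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    paths, scores = brute_force_paths(obs, params)
    return paths[int(np.argmax(scores))]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
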