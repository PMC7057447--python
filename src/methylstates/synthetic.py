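"""Synthetic array-style methylomes with known ground truth.

The generator emulates the structural features the caller relies on:
CpG positions clustered into dense islands separated by sparse open
sea; a hidden state that is spatially persistent along each chromosome
(a planted Markov chain over three strata: unmethylated, middle,
methylated); and noisy beta-values drawn from a normal around each
stratum mean truncated to [0, 1] — the emission law the caller itself
assumes.  (Clipping instead of truncating would deposit a point mass at
the boundaries — at a stratum mean of 0.95 with sd 0.05 about 16% of
draws — which is a genuinely bimodal feature no array produces.)

It deliberately does not emulate probe chemistry, position-dependent
noise, SNP artifacts or inter-sample variation; see the methods note
for what that implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ValidationError
from .profiles import IslandAnnotation, MethylationProfile, Platform

#: planted stratum indices and the site/region labels they correspond to
STRATUM_SITE_LABELS = ("UMS", "MMS", "FMS")
STRATUM_REGION_LABELS = ("UMR", "MMR", "FMR")


def _default_transition() -> tuple[tuple[float, ...], ...]:
    return (
        (0.95, 0.025, 0.025),
        (0.025, 0.95, 0.025),
        (0.025, 0.025, 0.95),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Layout and emission settings of the simulator.

    Defaults give ~3,500 CpGs on two chromosomes: 40 islands per
    chromosome (600-1200 bp long, probes every 20-100 bp) separated by
    open-sea blocks of 10-40 probes spaced 500-4000 bp, a planted
    3-state chain with self-transition 0.95, and stratum means
    0.05/0.5/0.95 with sd 0.05.
    """

    n_chroms: int = 2
    n_islands: int = 40
    island_len: tuple[int, int] = (600, 1200)
    island_cpg_spacing: tuple[int, int] = (20, 100)
    opensea_cpg_spacing: tuple[int, int] = (500, 4000)
    opensea_block_cpgs: tuple[int, int] = (10, 40)
    state_means: tuple[float, float, float] = (0.05, 0.5, 0.95)
    state_sds: tuple[float, float, float] = (0.05, 0.05, 0.05)
    state_transition: tuple[tuple[float, ...], ...] = field(
        default_factory=_default_transition
    )
    detection_p: float = 0.01
    platform: Platform = Platform.HM450K
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.state_transition, dtype=float)
        if P.shape != (3, 3) or (P < 0).any() or np.abs(P.sum(axis=1) - 1).max() > 1e-9:
            raise ValidationError("state_transition must be 3x3 row-stochastic")
        if list(self.state_means) != sorted(self.state_means):
            raise ValidationError("state_means must be ascending")
        for lo, hi in (
            self.island_len,
            self.island_cpg_spacing,
            self.opensea_cpg_spacing,
            self.opensea_block_cpgs,
        ):
            if lo <= 0 or hi < lo:
                raise ValidationError("ranges must be positive with lo <= hi")
        if self.island_len[1] < self.island_cpg_spacing[0]:
            raise ValidationError(
                "infeasible config: islands shorter than the minimum CpG spacing"
            )


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    return v / v.sum()


@dataclass
class SyntheticTruth:
    """A simulated profile together with its planted ground truth."""

    profile: MethylationProfile
    true_site_state: np.ndarray  # stratum index (0/1/2) per profile record
    true_regions: pd.DataFrame  # chrom, start, end (1-based inclusive), stratum, label
    islands: IslandAnnotation
    config: SimulationConfig


def simulate(config: SimulationConfig = SimulationConfig()) -> SyntheticTruth:
    """Generate a methylome; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    P = np.asarray(config.state_transition, dtype=float)
    pi0 = stationary_distribution(P)
    means = np.asarray(config.state_means, dtype=float)
    sds = np.asarray(config.state_sds, dtype=float)

    rows = []
    island_ivs: dict[str, list[list[int]]] = {}
    states_all: list[int] = []
    probe_counter = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        island_ivs[chrom] = []
        pos = 10_000
        positions: list[int] = []

        def opensea_block():
            nonlocal pos
            for _ in range(int(rng.integers(*_incl(config.opensea_block_cpgs)))):
                pos += int(rng.integers(*_incl(config.opensea_cpg_spacing)))
                positions.append(pos)

        opensea_block()
        for _ in range(config.n_islands):
            gap_into_island = int(rng.integers(*_incl(config.opensea_cpg_spacing)))
            start0 = pos + gap_into_island  # 0-based island start
            length = int(rng.integers(*_incl(config.island_len)))
            island_ivs[chrom].append([start0, start0 + length])
            p = start0
            while True:
                p += int(rng.integers(*_incl(config.island_cpg_spacing)))
                if p >= start0 + length:
                    break
                positions.append(p + 1)  # 1-based site position
            pos = start0 + length
            opensea_block()

        k = len(positions)
        if k == 0:
            continue
        states = np.empty(k, dtype=np.int64)
        states[0] = rng.choice(3, p=pi0)
        for i in range(1, k):
            states[i] = rng.choice(3, p=P[states[i - 1]])
        mu, sd = means[states], sds[states]
        beta = np.where(
            sd > 0,
            truncnorm.rvs(
                (0.0 - mu) / np.where(sd > 0, sd, 1.0),
                (1.0 - mu) / np.where(sd > 0, sd, 1.0),
                loc=mu,
                scale=np.where(sd > 0, sd, 1.0),
                random_state=rng,
            ),
            mu,
        )
        states_all.extend(states.tolist())
        for p, b in zip(positions, beta):
            rows.append((f"cg{probe_counter:08d}", chrom, p, float(b)))
            probe_counter += 1

    frame = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "beta"])
    frame["detection_p"] = config.detection_p
    profile = MethylationProfile(frame, platform=config.platform)
    true_state = np.asarray(states_all, dtype=np.int64)

    # maximal runs of constant stratum -> truth regions
    reg_rows = []
    df = profile.records
    for chrom in profile.chroms:
        idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        st = true_state[idx]
        pos_arr = df["pos"].to_numpy()[idx]
        brk = np.flatnonzero(st[:-1] != st[1:]) + 1
        for seg in np.split(np.arange(idx.size), brk):
            s = int(st[seg[0]])
            reg_rows.append(
                (
                    chrom,
                    int(pos_arr[seg[0]]),
                    int(pos_arr[seg[-1]]),
                    s,
                    STRATUM_REGION_LABELS[s],
                    len(seg),
                )
            )
    true_regions = pd.DataFrame(
        reg_rows, columns=["chrom", "start", "end", "stratum", "label", "n_cpg"]
    )
    islands = IslandAnnotation(
        {c: np.asarray(v, dtype=np.int64) for c, v in island_ivs.items()}
    )
    return SyntheticTruth(
        profile=profile,
        true_site_state=true_state,
        true_regions=true_regions,
        islands=islands,
        config=config,
    )


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    """Inclusive (lo, hi) range -> numpy integers() arguments."""
    return rng_pair[0], rng_pair[1] + 1
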