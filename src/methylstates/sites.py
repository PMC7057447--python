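"""Two-layer methylation-state calling at single CpG sites.

Layer 1 runs the two-state HMM on the beta-value chains and splits sites
into a low-methyl and a high-methyl class.  Each class is then examined
for bimodality: a class whose beta distribution is bimodal is re-split
by a second two-state HMM run on that class's sites alone (re-chained in
genomic order, initialization cutoff at the class median), while a
unimodal class is labeled wholesale.  The low class resolves to
{UMS, MMS} and the high class to {MMS, FMS}, yielding the three final
site labels: un-, middle- and full-methylated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from . import hmm
from .dip import dip_pvalue, dip_statistic
from .errors import InitializationError, ValidationError
from .profiles import MethylationProfile

logger = logging.getLogger(__name__)

UMS, MMS, FMS = "UMS", "MMS", "FMS"
SITE_LABELS = (UMS, MMS, FMS)


@dataclass(frozen=True)
class BimodalityConfig:
    """Settings of the bimodality gate between the two HMM layers.

    method
        "dip": Hartigan's dip statistic, bimodal iff the Monte-Carlo
        p-value (against the uniform null) is below ``alpha``.
        "kde_peaks": Gaussian KDE (Silverman bandwidth) on a fixed grid,
        bimodal iff at least two local maxima exist and the second
        highest reaches ``minor_peak_frac`` of the highest.
    min_n
        Below this sample size the verdict is unimodal by rule; a split
        supported by so few sites would not be trustworthy.
    n_boot
        Monte-Carlo replicates for the dip p-value.
    seed
        Seed of the dip null simulation (the only stochastic element;
        fixed by default so calls are reproducible).
    """

    method: str = "dip"
    alpha: float = 0.05
    min_n: int = 50
    n_boot: int = 200
    kde_gridsize: int = 512
    minor_peak_frac: float = 0.10
    seed: int = 715

    def __post_init__(self) -> None:
        if self.method not in ("dip", "kde_peaks"):
            raise ValidationError(f"unknown bimodality method {self.method!r}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class BimodalityVerdict:
    is_bimodal: bool
    statistic: float
    threshold: float
    method: str
    pvalue: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "is_bimodal": self.is_bimodal,
            "statistic": self.statistic,
            "threshold": self.threshold,
            "method": self.method,
            "pvalue": self.pvalue,
            "note": self.note,
        }


def assess_bimodality(
    values, config: BimodalityConfig = BimodalityConfig()
) -> BimodalityVerdict:
    """Decide whether a beta-value sample is bimodal.

    Samples smaller than ``config.min_n`` are declared unimodal with a
    warning.  Values must lie in [0, 1].
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size and ((x < 0).any() or (x > 1).any() or not np.isfinite(x).all()):
        raise ValidationError("bimodality input must be finite and within [0, 1]")
    if x.size < config.min_n:
        logger.warning(
            "bimodality: n=%d below min_n=%d, declaring unimodal", x.size, config.min_n
        )
        return BimodalityVerdict(
            is_bimodal=False,
            statistic=0.0,
            threshold=config.alpha if config.method == "dip" else config.minor_peak_frac,
            method=config.method,
            note=f"n={x.size} < min_n={config.min_n}; unimodal by rule",
        )

    if config.method == "dip":
        d = dip_statistic(x)
        p = dip_pvalue(d, x.size, n_boot=config.n_boot, rng=np.random.default_rng(config.seed))
        return BimodalityVerdict(
            is_bimodal=p < config.alpha,
            statistic=d,
            threshold=config.alpha,
            method="dip",
            pvalue=p,
        )

    # kde_peaks
    if np.ptp(x) == 0.0:
        return BimodalityVerdict(
            False, 0.0, config.minor_peak_frac, "kde_peaks", note="constant sample"
        )
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, config.kde_gridsize)
    dens = kde(grid)
    peaks, _ = find_peaks(dens)
    heights = np.sort(dens[peaks])[::-1]
    ratio = float(heights[1] / heights[0]) if heights.size >= 2 else 0.0
    return BimodalityVerdict(
        is_bimodal=heights.size >= 2 and ratio >= config.minor_peak_frac,
        statistic=ratio,
        threshold=config.minor_peak_frac,
        method="kde_peaks",
    )


@dataclass(frozen=True)
class CallerConfig:
    """Configuration shared by the two HMM layers and the gate."""

    hmm: hmm.HmmConfig = field(default_factory=hmm.HmmConfig)
    bimodality: BimodalityConfig = field(default_factory=BimodalityConfig)


@dataclass
class TwoLayerResult:
    """Per-position final labels plus full diagnostics of both layers."""

    labels: np.ndarray  # concatenated over chains, dtype object/str
    layer1_states: np.ndarray  # 0=LOW, 1=HIGH, concatenated
    layer1_fit: hmm.FitResult | None
    layer2_fits: dict[str, hmm.FitResult]
    verdicts: dict[str, BimodalityVerdict]

    def to_dict(self) -> dict:
        return {
            "layer1_fit": self.layer1_fit.to_dict() if self.layer1_fit else None,
            "layer2_fits": {k: v.to_dict() for k, v in self.layer2_fits.items()},
            "verdicts": {k: v.to_dict() for k, v in self.verdicts.items()},
            "label_counts": pd.Series(self.labels).value_counts().to_dict(),
        }


def two_layer_labels(
    chains: Sequence[np.ndarray],
    config: CallerConfig = CallerConfig(),
    labels: tuple[str, str, str] = SITE_LABELS,
) -> TwoLayerResult:
    """Run the full two-layer two-state procedure on observation chains.

    ``labels`` is the (low, middle, high) label triple — site labels for
    CpG calling, region labels when the observations are region means.
    The low layer-1 class maps to {low, middle}, the high class to
    {middle, high}; within a bimodal class the sub-state with the
    smaller fitted emission mean takes the lower label.
    """
    lo_lab, mid_lab, hi_lab = labels
    chains = [np.asarray(c, dtype=float).ravel() for c in chains]
    sizes = [c.size for c in chains]
    obs_all = np.concatenate(chains) if chains else np.array([])
    if obs_all.size == 0:
        raise ValidationError("no observations to label")

    # ---- layer 1: LOW/HIGH split
    layer1_fit: hmm.FitResult | None = None
    try:
        layer1_fit, paths = hmm.fit_and_decode(chains, config.hmm)
        layer1 = np.concatenate(paths)
    except InitializationError:
        # all observations fall on one side of the cutoff: single class
        side = hmm.LOW if obs_all[0] <= config.hmm.init_cutoff else hmm.HIGH
        logger.warning(
            "layer 1: all observations on one side of the %.2f cutoff; "
            "treating all as %s", config.hmm.init_cutoff, hmm.STATE_NAMES[side],
        )
        layer1 = np.full(obs_all.size, side, dtype=np.int8)

    final = np.empty(obs_all.size, dtype=object)
    layer2_fits: dict[str, hmm.FitResult] = {}
    verdicts: dict[str, BimodalityVerdict] = {}

    for side, pair in ((hmm.LOW, (lo_lab, mid_lab)), (hmm.HIGH, (mid_lab, hi_lab))):
        mask = layer1 == side
        if not mask.any():
            continue
        side_name = hmm.STATE_NAMES[side]
        values = obs_all[mask]
        verdict = assess_bimodality(values, config.bimodality)
        verdicts[side_name] = verdict
        fallback = pair[0] if side == hmm.LOW else pair[1]
        if not verdict.is_bimodal:
            final[mask] = fallback
            continue
        # layer 2: re-chain this class's sites per chromosome, split at
        # the class median
        sub_chains = []
        off = 0
        for size in sizes:
            sub = obs_all[off : off + size][mask[off : off + size]]
            if sub.size:
                sub_chains.append(sub)
            off += size
        cutoff = float(np.clip(np.median(values), 1e-6, 1 - 1e-6))
        sub_cfg = replace(config.hmm, init_cutoff=cutoff)
        try:
            fit2, sub_paths = hmm.fit_and_decode(sub_chains, sub_cfg)
        except InitializationError:
            logger.warning(
                "layer 2 (%s class): degenerate split at the class median; "
                "falling back to the unimodal label", side_name,
            )
            final[mask] = fallback
            continue
        layer2_fits[side_name] = fit2
        sub_states = np.concatenate(sub_paths)
        # sub-state with the smaller emission mean -> lower label
        order = np.argsort(fit2.params.means, kind="stable")
        state_to_label = {int(order[0]): pair[0], int(order[1]): pair[1]}
        final[mask] = [state_to_label[int(s)] for s in sub_states]

    return TwoLayerResult(
        labels=final,
        layer1_states=layer1,
        layer1_fit=layer1_fit,
        layer2_fits=layer2_fits,
        verdicts=verdicts,
    )


@dataclass
class SiteCallResult:
    """Site-state calls for one profile.

    ``frame`` has one row per retained CpG: probe_id, chrom, pos, beta,
    layer1_state (LOW/HIGH) and final_state (UMS/MMS/FMS), in genomic
    order.  ``diagnostics`` carries both layers' fit results and the
    bimodality verdicts, JSON-serializable.
    """

    frame: pd.DataFrame
    result: TwoLayerResult

    def diagnostics(self) -> dict:
        return self.result.to_dict()


def call_site_states(
    profile: MethylationProfile, config: CallerConfig = CallerConfig()
) -> SiteCallResult:
    """Call UMS/MMS/FMS at every CpG of a profile.

    The profile must be non-empty; chains are the per-chromosome
    beta-value sequences in genomic order.
    """
    if len(profile) == 0:
        raise ValidationError("cannot call states on an empty profile")
    chains = profile.beta_chains()
    res = two_layer_labels(chains, config, labels=SITE_LABELS)
    frame = profile.records.loc[:, ["probe_id", "chrom", "pos", "beta"]].copy()
    frame["layer1_state"] = [hmm.STATE_NAMES[s] for s in res.layer1_states]
    frame["final_state"] = res.labels.astype(str)
    return SiteCallResult(frame=frame, result=res)
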