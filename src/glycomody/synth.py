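"""Synthetic cohorts, peak tables, chromatograms and replicate data.

The generators in this module emulate the statistical structure of a plasma
N-glycomics biomarker study of HNF1A-MODY: four HNF1A variant groups
(damaging / VUS / benign / no mutation) with group sizes 18 / 5 / 8 / 289,
per-sample antennary fucosylation indexes that are lower in the damaging
group, hsCRP positively rank-correlated with the fucosylation traits, a
49-peak HILIC-UHPLC fluorescence peak table whose fucosylated /
non-fucosylated peak pairs encode the true indexes exactly, pooled-plasma
plate triplicates for repeatability QC, and a noisy monotone second-lab
replicate for interlaboratory concordance.

Every generator is a pure function of its parameters and a seed: the same
inputs always produce the same output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUPS",
    "SINGLE_TRAITS",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SD",
    "CohortSpec",
    "SampleRecord",
    "PeakSpec",
    "ChromatogramSpec",
    "generate_cohort",
    "cohort_to_frame",
    "cohort_to_peak_table",
    "default_template",
    "render_chromatogram",
    "generate_triplicates",
    "generate_second_lab",
    "calibrate_second_lab_noise",
]

#: HNF1A variant classification groups.
GROUPS = ("damaging", "vus", "benign", "none")

#: The five single antennary-fucosylation traits evaluated as biomarkers
#: (the A2FG2S2 index exists as an optional sixth trait, see
#: :mod:`glycomody.traits`).
SINGLE_TRAITS = ("A3FG3S2", "A3FG3S3", "FA3FG3S3", "A4FG4S4_I", "A4FG4S4_II")

#: Study cohort group sizes.
DEFAULT_GROUP_SIZES = {"damaging": 18, "vus": 5, "benign": 8, "none": 289}

# Illustrative group-wise index means/SDs.  The source study reports trait
# distributions only as dot plots, so these defaults are chosen to give a
# ~2 SD case/control separation with control means above the reported
# classification cutoffs; they are not measured clinical values.
_CONTROL_MEANS = {
    "A2FG2S2": 0.040,
    "A3FG3S2": 0.130,
    "A3FG3S3": 0.200,
    "FA3FG3S3": 0.090,
    "A4FG4S4_I": 0.060,
    "A4FG4S4_II": 0.080,
}
_DAMAGING_MEANS = {
    "A2FG2S2": 0.025,
    "A3FG3S2": 0.070,
    "A3FG3S3": 0.120,
    "FA3FG3S3": 0.050,
    "A4FG4S4_I": 0.030,
    "A4FG4S4_II": 0.040,
}
DEFAULT_GROUP_MEANS: dict[str, dict[str, float]] = {
    t: {
        "damaging": _DAMAGING_MEANS[t],
        "vus": _CONTROL_MEANS[t],
        "benign": _CONTROL_MEANS[t],
        "none": _CONTROL_MEANS[t],
    }
    for t in SINGLE_TRAITS
}
DEFAULT_GROUP_SD: dict[str, float] = {
    "A2FG2S2": 0.010,
    "A3FG3S2": 0.030,
    "A3FG3S3": 0.040,
    "FA3FG3S3": 0.020,
    "A4FG4S4_I": 0.015,
    "A4FG4S4_II": 0.020,
}

# Clinical-characteristics defaults per group: hsCRP mean/SD (mg/L),
# male fraction, age at recruitment mean/SD (years).
_CRP_MEAN_SD = {
    "damaging": (0.80, 1.32),
    "vus": (4.01, 6.30),
    "benign": (5.21, 5.75),
    "none": (3.79, 6.97),
}
_MALE_FRACTION = {"damaging": 0.28, "vus": 0.40, "benign": 0.50, "none": 0.52}
_AGE_MEAN_SD = {
    "damaging": (39.7, 17.4),
    "vus": (54.2, 14.2),
    "benign": (48.1, 11.2),
    "none": (45.6, 9.7),
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic study cohort.

    Parameters
    ----------
    n_damaging, n_vus, n_benign, n_none
        Group sizes (defaults: the study's 18 / 5 / 8 / 289).
    group_index_means
        ``trait -> group -> mean`` fucosylation index, each in [0, 1].
    group_index_sd
        ``trait -> SD`` of the index within every group (> 0).
    crp_trait_rho
        Target Spearman rank correlation between hsCRP and the traits,
        in [-1, 1], realised through a Gaussian copula.
    trait_latent_share
        Fraction (in [0, 1]) of each trait's latent variance carried by a
        per-sample shared factor; 0 makes traits mutually independent.
    seed
        Seed for the generator's random stream.
    """

    n_damaging: int = 18
    n_vus: int = 5
    n_benign: int = 8
    n_none: int = 289
    group_index_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_GROUP_MEANS
    )
    group_index_sd: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_GROUP_SD
    )
    crp_trait_rho: float = 0.3
    trait_latent_share: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_damaging", "n_vus", "n_benign", "n_none"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for trait, per_group in self.group_index_means.items():
            for group, mean in per_group.items():
                if not 0.0 <= mean <= 1.0:
                    raise ValueError(
                        f"mean index for {trait}/{group} must be in [0, 1], got {mean}"
                    )
            if trait not in self.group_index_sd:
                raise ValueError(f"missing SD for trait {trait!r}")
        for trait, sd in self.group_index_sd.items():
            if sd <= 0:
                raise ValueError(f"SD for {trait!r} must be > 0, got {sd}")
        if not -1.0 <= self.crp_trait_rho <= 1.0:
            raise ValueError("crp_trait_rho must be in [-1, 1]")
        if not 0.0 <= self.trait_latent_share <= 1.0:
            raise ValueError("trait_latent_share must be in [0, 1]")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "damaging": self.n_damaging,
            "vus": self.n_vus,
            "benign": self.n_benign,
            "none": self.n_none,
        }

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.group_index_means)


@dataclass
class SampleRecord:
    """One synthetic study participant."""

    sample_id: str
    group: str
    sex: str
    age: float
    crp: float
    true_traits: dict[str, float]


def _truncnorm_ppf(q: np.ndarray, mean: float, sd: float) -> np.ndarray:
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return sps.truncnorm.ppf(q, a, b, loc=mean, scale=sd)


def _lognorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-normal shape/scale matching a target arithmetic mean and SD."""
    s2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return math.sqrt(s2), math.exp(mu)


def generate_cohort(spec: CohortSpec | None = None) -> list[SampleRecord]:
    """Draw a synthetic cohort with the configured group structure.

    Trait values are truncated-normal on [0, 1] per group, generated through
    a Gaussian copula: each sample carries a latent standard-normal factor
    shared across traits (weight ``trait_latent_share``), and hsCRP is
    coupled to that factor so its rank correlation with the traits
    approaches ``crp_trait_rho`` under a log-normal CRP marginal.

    Returns the samples in group order damaging, vus, benign, none.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    traits = spec.traits
    share = spec.trait_latent_share
    if spec.crp_trait_rho != 0.0:
        if share == 0.0:
            raise ValueError(
                "crp_trait_rho != 0 requires trait_latent_share > 0 "
                "(CRP couples to the shared trait factor)"
            )
        # Gaussian-copula Pearson correlation reproducing a Spearman target,
        # divided by the shared factor's loading on each trait.
        rho_latent = 2.0 * math.sin(math.pi * spec.crp_trait_rho / 6.0)
        rho_crp = float(np.clip(rho_latent / math.sqrt(share), -0.999, 0.999))
    else:
        rho_crp = 0.0

    records: list[SampleRecord] = []
    counter = 0
    for group in GROUPS:
        n = spec.group_sizes[group]
        z = rng.standard_normal(n)
        trait_values: dict[str, np.ndarray] = {}
        for trait in traits:
            eps = rng.standard_normal(n)
            w = math.sqrt(share) * z + math.sqrt(1.0 - share) * eps
            trait_values[trait] = _truncnorm_ppf(
                sps.norm.cdf(w),
                spec.group_index_means[trait][group],
                spec.group_index_sd[trait],
            )
        eta = rng.standard_normal(n)
        v = rho_crp * z + math.sqrt(1.0 - rho_crp**2) * eta
        shape, scale = _lognorm_params(*_CRP_MEAN_SD[group])
        crp = sps.lognorm.ppf(sps.norm.cdf(v), s=shape, scale=scale)
        sexes = np.where(rng.random(n) < _MALE_FRACTION[group], "M", "F")
        age_mean, age_sd = _AGE_MEAN_SD[group]
        ages = np.clip(rng.normal(age_mean, age_sd, n), 18.0, 90.0)
        for i in range(n):
            counter += 1
            records.append(
                SampleRecord(
                    sample_id=f"S{counter:04d}",
                    group=group,
                    sex=str(sexes[i]),
                    age=float(ages[i]),
                    crp=float(crp[i]),
                    true_traits={t: float(trait_values[t][i]) for t in traits},
                )
            )
    return records


def cohort_to_frame(cohort: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabular view of a cohort (one row per sample, one column per trait)."""
    rows = []
    for rec in cohort:
        row = {
            "sample_id": rec.sample_id,
            "group": rec.group,
            "sex": rec.sex,
            "age": rec.age,
            "crp": rec.crp,
        }
        row.update(rec.true_traits)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Peak-table synthesis


def default_template() -> dict[str, float]:
    """Baseline relative abundances for the 49 modeled glycan peaks.

    The eleven analysis peaks (six antennary-fucosylated peaks and their
    non-fucosylated counterparts) carry fixed backbone abundances; the
    remaining peaks are low-level fillers so that a full 49-peak profile is
    produced.  Values are normalized to sum to 1.
    """
    template: dict[str, float] = {}
    # Fillers: small, deterministic, distinct values.
    for k in range(1, 50):
        template[f"p{k}"] = 0.25 + 0.05 * ((7 * k) % 11)
    # Major non-analysis peaks (relative intensity above 1%).
    template["p28"] = 16.0  # most abundant peak
    template["p34"] = 2.5
    template["p46"] = 1.8
    # Analysis peaks: non-fucosylated counterparts ...
    template["p25"] = 3.8   # A2G2S2
    template["p32"] = 4.5   # A3G3S2
    template["p38"] = 3.2   # A3G3S3
    template["p41"] = 2.3   # FA3G3S3
    template["p47"] = 1.9   # A4G4S4 (shared by both A4FG4S4 isomer traits)
    # ... and fucosylated peaks at control-like levels (overwritten per
    # sample from the true index, kept here so the template alone is a
    # plausible profile).
    template["p29"] = 0.16  # A2FG2S2
    template["p35"] = 0.67  # A3FG3S2
    template["p42"] = 0.80  # A3FG3S3
    template["p44"] = 0.23  # FA3FG3S3
    template["p48"] = 0.12  # A4FG4S4_I
    template["p49"] = 0.17  # A4FG4S4_II
    total = sum(template.values())
    return {k: v / total for k, v in template.items()}


def cohort_to_peak_table(
    cohort: Sequence[SampleRecord],
    template: Mapping[str, float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    pairings: Sequence | None = None,
) -> pd.DataFrame:
    """Invert the trait construction: cohort -> sample x peak table.

    For each trait the fucosylated / non-fucosylated peak-pair abundances
    are set so that recomputing the fucosylation index from the (noiseless)
    table reproduces the sample's true index exactly.  Pairs with an
    unshared counterpart keep the template's combined pair abundance and
    split it as ``(index, 1 - index)``; when two traits share one
    counterpart peak (the two A4FG4S4 isomers), the counterpart is held at
    its template abundance and each fucosylated peak is solved as
    ``nonfuc * index / (1 - index)``.

    Multiplicative noise with coefficient of variation ``noise_cv`` is then
    applied per cell and each row renormalized to sum to 1 (the index is a
    within-row ratio, so renormalization never changes the noiseless
    round trip).
    """
    from .traits import DEFAULT_PAIRINGS_ALL  # deferred: avoid import cycle

    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    template = dict(template) if template is not None else default_template()
    pairings = list(pairings) if pairings is not None else list(DEFAULT_PAIRINGS_ALL)
    trait_names = set()
    for rec in cohort:
        trait_names.update(rec.true_traits)
    pairings = [p for p in pairings if p.trait_name in trait_names]
    for p in pairings:
        for label in (*p.fucosylated_peaks, *p.nonfucosylated_peaks):
            if label not in template:
                raise ValueError(
                    f"template missing paired peak {label!r} for trait {p.trait_name!r}"
                )
    counterpart_use: dict[str, int] = {}
    for p in pairings:
        for label in p.nonfucosylated_peaks:
            counterpart_use[label] = counterpart_use.get(label, 0) + 1

    rng = np.random.default_rng(seed)
    labels = list(template)
    base = np.array([template[k] for k in labels])
    idx = {k: i for i, k in enumerate(labels)}
    rows = np.tile(base, (len(cohort), 1))

    for r, rec in enumerate(cohort):
        for p in pairings:
            i_true = rec.true_traits[p.trait_name]
            if not 0.0 <= i_true < 1.0:
                raise ValueError(
                    f"fucosylation index for {p.trait_name!r} must be in [0, 1); "
                    f"got {i_true} for sample {rec.sample_id}"
                )
            fuc_ix = [idx[k] for k in p.fucosylated_peaks]
            non_ix = [idx[k] for k in p.nonfucosylated_peaks]
            fuc_base = base[fuc_ix]
            non_total = float(base[non_ix].sum())
            shared = any(counterpart_use[k] > 1 for k in p.nonfucosylated_peaks)
            if shared:
                fuc_total = non_total * i_true / (1.0 - i_true)
            else:
                combined = float(fuc_base.sum()) + non_total
                fuc_total = combined * i_true
                rows[r, non_ix] = base[non_ix] / non_total * combined * (1.0 - i_true)
            # split the fucosylated mass across its peaks pro rata
            rows[r, fuc_ix] = fuc_base / fuc_base.sum() * fuc_total

    if noise_cv > 0:
        factors = np.clip(1.0 + noise_cv * rng.standard_normal(rows.shape), 0.0, None)
        rows = rows * factors
    rows = rows / rows.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        rows, index=pd.Index([rec.sample_id for rec in cohort], name="sample_id"),
        columns=labels,
    )


# ---------------------------------------------------------------------------
# Chromatogram rendering


@dataclass(frozen=True)
class PeakSpec:
    """One rendered chromatographic peak: a Gaussian of given area."""

    label: str
    rt: float       # retention time, minutes
    sigma: float    # Gaussian width, minutes
    area: float     # a.u. * min


@dataclass
class ChromatogramSpec:
    """Parameters of a rendered fluorescence trace.

    The trace is a sum of Gaussian peaks over a linearly drifting baseline
    with white Gaussian noise, sampled uniformly on [t_start, t_end]
    minutes (the default span emulates a 70-min HILIC-UHPLC run).
    ``time_warp`` gives ascending-power coefficients ``c`` of a polynomial
    perturbation applied to peak positions: a peak nominally at ``t``
    appears at ``t + sum_k c[k] * t**k``.
    """

    peaks: Sequence[PeakSpec] = ()
    baseline_level: float = 0.0
    baseline_drift: float = 0.0
    noise_sd: float = 0.0
    sampling_interval: float = 0.005
    t_start: float = 0.0
    t_end: float = 70.0
    time_warp: Sequence[float] = ()

    def validate(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rts = [p.rt for p in self.peaks]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("peak retention times must be strictly increasing")
        labels = [p.label for p in self.peaks]
        if len(set(labels)) != len(labels):
            raise ValueError("overlapping identical peak labels")
        for p in self.peaks:
            if p.sigma <= 0:
                raise ValueError(f"sigma must be > 0 for peak {p.label!r}")
            if p.area < 0:
                raise ValueError(f"area must be >= 0 for peak {p.label!r}")

    def warped_rt(self, rt: float) -> float:
        return rt + sum(c * rt**k for k, c in enumerate(self.time_warp))


def render_chromatogram(spec: ChromatogramSpec, seed: int = 0):
    """Render a synthetic fluorescence trace from a :class:`ChromatogramSpec`.

    With zero noise and zero baseline the numeric integral of the trace
    equals the sum of configured peak areas (up to Gaussian tail truncation
    at the run boundaries).
    """
    from .chromatogram import Chromatogram  # deferred: avoid import cycle

    spec.validate()
    rng = np.random.default_rng(seed)
    t = np.arange(spec.t_start, spec.t_end + spec.sampling_interval / 2,
                  spec.sampling_interval)
    y = spec.baseline_level + spec.baseline_drift * t
    for p in spec.peaks:
        mu = spec.warped_rt(p.rt)
        y = y + p.area / (p.sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((t - mu) / p.sigma) ** 2
        )
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, t.size)
    return Chromatogram(time=t, intensity=y)


# ---------------------------------------------------------------------------
# Replicates: plate triplicates and second-lab data


def generate_triplicates(
    standard_row: pd.Series,
    n_plates: int,
    intra_cv: float = 0.05,
    inter_cv: float = 0.07,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Pooled-plasma standard replicates across plates.

    Each plate carries ``n_replicates`` rows of the standard profile with a
    per-plate, per-peak multiplicative offset (CV ``inter_cv``) and
    per-replicate multiplicative noise (CV ``intra_cv``).  Returns a frame
    with a ``plate`` column followed by the peak columns.
    """
    if intra_cv < 0 or inter_cv < 0:
        raise ValueError("CVs must be >= 0")
    if n_plates < 0:
        raise ValueError("n_plates must be >= 0")
    rng = np.random.default_rng(seed)
    peaks = list(standard_row.index)
    base = standard_row.to_numpy(dtype=float)
    records, plates, index = [], [], []
    for plate in range(1, n_plates + 1):
        offset = 1.0 + inter_cv * rng.standard_normal(len(peaks))
        for rep in range(1, n_replicates + 1):
            noise = 1.0 + intra_cv * rng.standard_normal(len(peaks))
            records.append(np.clip(base * offset * noise, 0.0, None))
            plates.append(f"plate{plate:02d}")
            index.append(f"plate{plate:02d}_rep{rep}")
    out = pd.DataFrame(records, index=pd.Index(index, name="replicate_id"),
                       columns=peaks)
    out.insert(0, "plate", plates)
    return out


def _check_monotone(transform: Callable[[np.ndarray], np.ndarray],
                    values: np.ndarray) -> None:
    grid = np.unique(values)
    if grid.size < 2:
        return
    fx = np.asarray(transform(grid), dtype=float)
    d = np.diff(fx)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("second-lab transform must be strictly monotone")


def generate_second_lab(
    traits: pd.DataFrame,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Second-laboratory replicate of a trait table.

    Applies a strictly monotone transform column-wise (default: percent
    scale, ``x -> 100 x``, emulating a relative-abundance representation)
    and adds Gaussian noise whose SD is ``noise_sd`` times the SD of the
    transformed column.  With ``noise_sd = 0`` the Spearman correlation
    with the input is exactly +/-1 for any monotone transform.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    transform = transform or (lambda x: 100.0 * x)
    rng = np.random.default_rng(seed)
    out = {}
    for col in traits.columns:
        x = traits[col].to_numpy(dtype=float)
        _check_monotone(transform, x[np.isfinite(x)])
        fx = np.asarray(transform(x), dtype=float)
        if noise_sd > 0:
            scale = float(np.nanstd(fx))
            fx = fx + noise_sd * scale * rng.standard_normal(fx.size)
        out[col] = fx
    return pd.DataFrame(out, index=traits.index)


def _mean_spearman(x_ranks: np.ndarray, second: np.ndarray) -> float:
    # Spearman of x against each row of `second` via rank-Pearson.
    ranks = sps.rankdata(second, axis=1)
    xc = x_ranks - x_ranks.mean()
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    num = rc @ xc
    den = np.sqrt((rc**2).sum(axis=1) * (xc**2).sum())
    return float(np.mean(num / den))


def calibrate_second_lab_noise(
    values: np.ndarray | pd.Series,
    target_rho: float,
    n_reps: int = 60,
    seed: int = 0,
    tol: float = 0.002,
    max_iter: int = 40,
) -> float:
    """Noise level for :func:`generate_second_lab` hitting a Spearman target.

    Uses common random numbers so the mean Spearman correlation is a
    monotone decreasing function of the noise SD, then bisects.  Returns
    the ``noise_sd`` (as a fraction of the transformed column's SD) whose
    Monte-Carlo mean correlation over ``n_reps`` replicates is within
    ``tol`` of ``target_rho``.
    """
    if not 0.0 < target_rho < 1.0:
        raise ValueError("target_rho must be in (0, 1)")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 values to calibrate")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_reps, x.size))
    sd = float(np.std(x))
    x_ranks = sps.rankdata(x)

    def mean_rho(s: float) -> float:
        return _mean_spearman(x_ranks, x[None, :] + s * sd * eps)

    lo, hi = 0.0, 1.0
    while mean_rho(hi) > target_rho:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("calibration failed to bracket the target")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = mean_rho(mid)
        if abs(r - target_rho) < tol:
            return mid
        if r > target_rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
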