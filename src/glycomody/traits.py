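"""Peak-area normalization and antennary fucosylation traits.

A sample's glycan profile is reduced to *fucosylation indexes*: for each
antennary-fucosylated structure, the relative area of its peak(s) divided
by the combined relative area of the fucosylated peak(s) and the
non-fucosylated counterpart peak(s),

    index = fuc / (fuc + nonfuc),

a fraction in [0, 1] that is invariant to any per-sample scaling.  The
*derived* trait is the arithmetic mean of a configured set of single
indexes and summarizes plasma-wide antennary fucosylation.

Default pairings map each fucosylated peak to the counterpart of the same
composition without the antennary fucose: A3FG3S2 (p35) <-> A3G3S2 (p32),
A3FG3S3 (p42) <-> A3G3S3 (p38), FA3FG3S3 (p44) <-> FA3G3S3 (p41), and the
two A4FG4S4 isomers (p48, p49) each <-> A4G4S4 (p47).  An A2FG2S2 (p29)
<-> A2G2S2 (p25) pairing is available but excluded from the derived trait
by default.  All pairings are configuration-overridable because peak
assignment is instrument- and study-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TraitPairing",
    "DEFAULT_PAIRINGS",
    "DEFAULT_PAIRINGS_ALL",
    "DEFAULT_DERIVED_MEMBERS",
    "DEFAULT_ANALYSIS_PEAKS",
    "DERIVED_TRAIT",
    "PeakNormalizer",
    "FucosylationTraits",
    "normalize_peak_table",
    "fucosylation_index",
    "compute_traits",
    "relative_abundance",
    "load_pairings",
]

DERIVED_TRAIT = "derived"


@dataclass(frozen=True)
class TraitPairing:
    """One fucosylation index: fucosylated peaks vs their counterparts."""

    trait_name: str
    fucosylated_peaks: tuple[str, ...]
    nonfucosylated_peaks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.fucosylated_peaks or not self.nonfucosylated_peaks:
            raise ValueError(f"{self.trait_name}: both peak lists must be non-empty")
        if set(self.fucosylated_peaks) & set(self.nonfucosylated_peaks):
            raise ValueError(f"{self.trait_name}: peak lists must be disjoint")


#: The five single traits evaluated as biomarkers.
DEFAULT_PAIRINGS: tuple[TraitPairing, ...] = (
    TraitPairing("A3FG3S2", ("p35",), ("p32",)),
    TraitPairing("A3FG3S3", ("p42",), ("p38",)),
    TraitPairing("FA3FG3S3", ("p44",), ("p41",)),
    TraitPairing("A4FG4S4_I", ("p48",), ("p47",)),
    TraitPairing("A4FG4S4_II", ("p49",), ("p47",)),
)

#: All six antennary-fucosylated structures, including the optional A2FG2S2.
DEFAULT_PAIRINGS_ALL: tuple[TraitPairing, ...] = (
    TraitPairing("A2FG2S2", ("p29",), ("p25",)),
) + DEFAULT_PAIRINGS

#: Members of the derived (averaged) trait.
DEFAULT_DERIVED_MEMBERS: tuple[str, ...] = tuple(p.trait_name for p in DEFAULT_PAIRINGS)

#: The eleven analysis peaks entering the normalization total.
DEFAULT_ANALYSIS_PEAKS: tuple[str, ...] = tuple(
    sorted(
        {p for pr in DEFAULT_PAIRINGS_ALL for p in pr.fucosylated_peaks}
        | {p for pr in DEFAULT_PAIRINGS_ALL for p in pr.nonfucosylated_peaks},
        key=lambda s: int(s[1:]),
    )
)


class PeakNormalizer(BaseEstimator, TransformerMixin):
    """Normalize raw peak areas to relative areas over the analysis peaks.

    Each row is divided by its summed area over ``analysis_peaks`` (all
    columns when None), so the analysis peaks of a valid row sum to 1.
    Rows whose analysis-peak total is zero cannot be normalized; they are
    returned as NaN and recorded in ``invalid_rows_``.
    """

    def __init__(self, analysis_peaks: Sequence[str] | None = None):
        self.analysis_peaks = analysis_peaks

    def fit(self, X: pd.DataFrame, y=None) -> "PeakNormalizer":
        peaks = list(self.analysis_peaks) if self.analysis_peaks is not None \
            else list(X.columns)
        missing = [p for p in peaks if p not in X.columns]
        if missing:
            raise ValueError(f"missing analysis peak column(s): {missing}")
        if (X[peaks].to_numpy() < 0).any():
            raise ValueError("raw areas must be >= 0")
        self.analysis_peaks_ = peaks
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        peaks = self.analysis_peaks_
        totals = X[peaks].sum(axis=1)
        invalid = totals <= 0
        self.invalid_rows_ = list(X.index[invalid])
        out = X[peaks].div(totals.where(~invalid), axis=0)
        return out


def normalize_peak_table(
    raw_areas: pd.DataFrame, analysis_peaks: Sequence[str] | None = None
) -> tuple[pd.DataFrame, list]:
    """Functional wrapper over :class:`PeakNormalizer`.

    Returns the normalized table (restricted to the analysis peaks) and
    the row ids flagged invalid (zero analysis-peak total, NaN in output).
    """
    norm = PeakNormalizer(analysis_peaks).fit(raw_areas)
    out = norm.transform(raw_areas)
    return out, norm.invalid_rows_


def fucosylation_index(fuc_area, nonfuc_area):
    """``fuc / (fuc + nonfuc)``, in [0, 1]; NaN where both areas are zero.

    Accepts scalars or aligned arrays/Series; negative areas are a
    contract violation and raise.
    """
    fuc = np.asarray(fuc_area, dtype=float)
    non = np.asarray(nonfuc_area, dtype=float)
    if (fuc < 0).any() or (non < 0).any():
        raise ValueError("areas must be >= 0")
    total = fuc + non
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, fuc / total, np.nan)
    if np.isscalar(fuc_area) and np.isscalar(nonfuc_area):
        return float(out)
    return out


class FucosylationTraits(BaseEstimator, TransformerMixin):
    """Compute single fucosylation indexes and the derived trait.

    Transform maps a normalized sample x peak table to a sample x trait
    table: one column per pairing (``fuc_sum / (fuc_sum + nonfuc_sum)``)
    plus a ``derived`` column averaging ``derived_members``.  A sample
    with any missing member index gets a missing derived value — the
    derived trait's definition never varies across samples.
    """

    def __init__(self, pairings: Sequence[TraitPairing] | None = None,
                 derived_members: Sequence[str] | None = None):
        self.pairings = pairings
        self.derived_members = derived_members

    def fit(self, X: pd.DataFrame, y=None) -> "FucosylationTraits":
        pairings = tuple(self.pairings) if self.pairings is not None \
            else DEFAULT_PAIRINGS_ALL
        names = [p.trait_name for p in pairings]
        if self.derived_members is not None:
            members = tuple(self.derived_members)
        elif self.pairings is None:
            members = DEFAULT_DERIVED_MEMBERS
        else:  # custom pairings: average everything by default
            members = tuple(n for n in names if n in DEFAULT_DERIVED_MEMBERS) \
                or tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in pairings")
        unknown = set(members) - set(names)
        if unknown:
            raise ValueError(f"derived member(s) not among pairings: {sorted(unknown)}")
        for p in pairings:
            for label in (*p.fucosylated_peaks, *p.nonfucosylated_peaks):
                if label not in X.columns:
                    raise ValueError(
                        f"unknown peak label {label!r} in pairing {p.trait_name!r}"
                    )
        self.pairings_ = pairings
        self.derived_members_ = members
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=X.index)
        for p in self.pairings_:
            fuc = X[list(p.fucosylated_peaks)].sum(axis=1, skipna=False)
            non = X[list(p.nonfucosylated_peaks)].sum(axis=1, skipna=False)
            out[p.trait_name] = fucosylation_index(fuc, non)
        members = list(self.derived_members_)
        if members:
            out[DERIVED_TRAIT] = out[members].mean(axis=1, skipna=False)
        return out


def compute_traits(
    table: pd.DataFrame,
    pairings: Sequence[TraitPairing] | None = None,
    derived_members: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`FucosylationTraits`."""
    return FucosylationTraits(pairings, derived_members).fit(table).transform(table)


def relative_abundance(table: pd.DataFrame, peak: str) -> pd.Series:
    """A normalized peak column on the percent scale (x100).

    This is the relative-abundance representation (percentage of the total
    integrated analysis-peak area) used when comparing against studies that
    report percentages rather than fucosylation indexes.
    """
    if peak not in table.columns:
        raise KeyError(f"peak {peak!r} not present in the table")
    return table[peak] * 100.0


def load_pairings(path) -> tuple[tuple[TraitPairing, ...], tuple[str, ...]]:
    """Read a pairing config (YAML): trait -> peak lists, plus derived members.

    Expected structure::

        traits:
          A3FG3S2: {fucosylated: [p35], nonfucosylated: [p32]}
          ...
        derived: [A3FG3S2, ...]
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "traits" not in doc:
        raise ValueError("pairing config must contain a 'traits' mapping")
    pairings = tuple(
        TraitPairing(name, tuple(entry["fucosylated"]), tuple(entry["nonfucosylated"]))
        for name, entry in doc["traits"].items()
    )
    derived = tuple(doc.get("derived") or (p.trait_name for p in pairings))
    return pairings, derived
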