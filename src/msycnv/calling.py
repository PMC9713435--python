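"""Replicate-merged copy-number calling and Y-profile classification.

Every reported sample is tested at least in duplicate.  Wells carrying any
QC flag are excluded, as are wells deviating noticeably from the replicate
median; the per-sample, per-gene copy number is the mean over the passing
wells, and a sample falls back to "needs retest" when fewer than two wells
survive.  Copy numbers are discussed as rounded integers (halves away from
zero), but the continuous means are retained for cohort statistics because
ddPCR measures a continuous ratio for a biologically discrete quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .droplet import GENES, CNEstimate, QCFlag

#: Replicate wells further than this many copies from the replicate median
#: are treated as "noticeably low or high" and excluded (configurable).
MAX_REPLICATE_DEVIATION = 1.5

#: Fractional-part band in which a rounded CN call is considered borderline.
BORDERLINE_BAND = (0.4, 0.6)


def round_cn(mean_cn: float) -> int:
    """Round a mean copy number to the nearest integer, halves away from zero."""
    if mean_cn < 0:
        raise ValueError("mean_cn must be >= 0")
    return int(math.floor(mean_cn + 0.5))


def is_borderline(mean_cn: float, band: tuple[float, float] = BORDERLINE_BAND) -> bool:
    """True when the fractional part sits in the ambiguous rounding band."""
    frac = mean_cn - math.floor(mean_cn)
    return band[0] <= frac <= band[1]


@dataclass(frozen=True)
class GeneCall:
    """Replicate-merged call for one sample x gene."""

    mean_cn: float | None
    rounded_cn: int | None
    n_passing: int
    n_wells: int
    needs_retest: bool
    borderline: bool = False

    @property
    def callable(self) -> bool:
        return self.mean_cn is not None


def aggregate_replicates(
    wells: Sequence[CNEstimate],
    max_deviation: float = MAX_REPLICATE_DEVIATION,
) -> GeneCall:
    """Merge replicate wells for one sample x gene.

    QC-flagged wells are excluded first; among the remainder, wells whose CN
    deviates from the replicate median by more than ``max_deviation`` copies
    are excluded as noticeably low/high.  Exclusions are reflected in
    ``n_passing`` versus ``n_wells`` — nothing is silently dropped.
    """
    if not wells:
        raise ValueError("at least one well required")
    clean = [w for w in wells if w.passed]
    if len(clean) >= 2 and max_deviation is not None:
        med = float(np.median([w.cn for w in clean]))
        clean = [w for w in clean if abs(w.cn - med) <= max_deviation]
    n_passing = len(clean)
    if n_passing == 0:
        return GeneCall(None, None, 0, len(wells), needs_retest=True)
    mean = float(np.mean([w.cn for w in clean]))
    return GeneCall(
        mean_cn=mean,
        rounded_cn=round_cn(mean),
        n_passing=n_passing,
        n_wells=len(wells),
        needs_retest=n_passing < 2,
        borderline=is_borderline(mean),
    )


@dataclass
class SampleProfile:
    """Per-sample CN vector across assayed genes plus cohort metadata."""

    sample_id: str
    breed: str = ""
    cohort: str = "normal"
    calls: dict[str, GeneCall] = field(default_factory=dict)

    def mean(self, gene: str) -> float | None:
        call = self.calls.get(gene)
        return call.mean_cn if call is not None else None

    def rounded(self, gene: str) -> int | None:
        call = self.calls.get(gene)
        return call.rounded_cn if call is not None else None


class ProfileCategory(str, Enum):
    NORMAL = "NORMAL"
    Y_DELETION = "Y_DELETION"
    SRY_NEG_DSD = "SRY_NEG_DSD"
    SRY_RBMY_AMPLIFIED = "SRY_RBMY_AMPLIFIED"
    MULTI_GENE_OUTLIER = "MULTI_GENE_OUTLIER"


@dataclass(frozen=True)
class ProfileClass:
    category: ProfileCategory
    evidence: dict[str, str]


class UnclassifiableProfileError(ValueError):
    """SRY and RBMY calls are prerequisites for Y-profile classification."""


def classify_y_profile(
    profile: SampleProfile,
    cohort_reference: Mapping[str, tuple[float, float]] | None = None,
    outlier_min_genes: int = 4,
    outlier_sd_mult: float = 3.0,
) -> ProfileClass:
    """Classify a sample's Y copy-number profile.

    Precedence: complete Y deletion (all assayed genes round to zero), then
    SRY-negative DSD (SRY = 0 with a single RBMY copy), then SRY/RBMY
    amplification (SRY >= 2), then multi-gene high-CN outlier (at least
    ``outlier_min_genes`` genes above cohort mean + ``outlier_sd_mult``*SD,
    requires ``cohort_reference`` = {gene: (mean, sd)}), else normal.
    Borderline rounding (fraction in 0.4-0.6) is recorded as evidence rather
    than silently resolving the call either way.
    """
    rounded = {g: c.rounded_cn for g, c in profile.calls.items() if c.callable}
    if "SRY" not in rounded or "RBMY" not in rounded:
        raise UnclassifiableProfileError(
            f"{profile.sample_id}: SRY and RBMY calls required for classification"
        )
    evidence: dict[str, str] = {
        g: "borderline rounding"
        for g, c in profile.calls.items()
        if c.callable and c.borderline
    }
    if all(cn == 0 for cn in rounded.values()):
        evidence["*"] = "no assay amplified"
        return ProfileClass(ProfileCategory.Y_DELETION, evidence)
    if rounded["SRY"] == 0 and rounded["RBMY"] == 1:
        evidence["SRY"] = "absent"
        evidence["RBMY"] = "single copy"
        return ProfileClass(ProfileCategory.SRY_NEG_DSD, evidence)
    if rounded["SRY"] >= 2:
        evidence["SRY"] = f"amplified (CN={rounded['SRY']})"
        if rounded["RBMY"] != 2:
            evidence["RBMY"] = f"deviant (CN={rounded['RBMY']})"
        return ProfileClass(ProfileCategory.SRY_RBMY_AMPLIFIED, evidence)
    if cohort_reference is not None:
        high = [
            g
            for g, (mu, sd) in cohort_reference.items()
            if g in profile.calls
            and profile.calls[g].callable
            and sd > 0
            and profile.calls[g].mean_cn > mu + outlier_sd_mult * sd
        ]
        if len(high) >= outlier_min_genes:
            for g in high:
                evidence[g] = "exceeds cohort mean + {:.1f} SD".format(outlier_sd_mult)
            return ProfileClass(ProfileCategory.MULTI_GENE_OUTLIER, evidence)
    return ProfileClass(ProfileCategory.NORMAL, evidence)


def build_profiles(
    estimates: Mapping[tuple[str, str], Sequence[CNEstimate]],
    metadata: pd.DataFrame | None = None,
    max_deviation: float = MAX_REPLICATE_DEVIATION,
) -> list[SampleProfile]:
    """Aggregate per-well estimates into SampleProfiles.

    ``estimates`` maps (sample_id, gene) to that sample's replicate wells
    (see :func:`msycnv.droplet.estimates_from_table`).  ``metadata`` may
    supply ``sample_id, breed, cohort`` columns.
    """
    meta: dict[str, tuple[str, str]] = {}
    if metadata is not None:
        for rec in metadata.itertuples(index=False):
            meta[str(rec.sample_id)] = (
                str(getattr(rec, "breed", "")),
                str(getattr(rec, "cohort", "normal")),
            )
    profiles: dict[str, SampleProfile] = {}
    for (sample_id, gene), wells in estimates.items():
        if sample_id not in profiles:
            breed, cohort = meta.get(sample_id, ("", "normal"))
            profiles[sample_id] = SampleProfile(sample_id, breed, cohort)
        profiles[sample_id].calls[gene] = aggregate_replicates(wells, max_deviation)
    return list(profiles.values())


def profiles_frame(profiles: Iterable[SampleProfile], genes: Sequence[str] = GENES) -> pd.DataFrame:
    """Flatten profiles to one wide row per sample (mean and rounded CN)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample_id": p.sample_id,
            "breed": p.breed,
            "cohort": p.cohort,
        }
        for g in genes:
            call = p.calls.get(g)
            row[f"{g}_mean"] = call.mean_cn if call and call.callable else np.nan
            row[f"{g}_cn"] = call.rounded_cn if call and call.callable else pd.NA
            row[f"{g}_needs_retest"] = bool(call.needs_retest) if call else True
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(
    profiles: pd.DataFrame, group_by: str, genes: Sequence[str] = GENES
) -> pd.DataFrame:
    """Per-group mean and SD of unrounded sample means, one row per group.

    SD is reported as NaN ("n/a") for single-sample groups.  Column order
    follows the canonical gene order.
    """
    if group_by not in profiles.columns:
        raise KeyError(f"unknown grouping label {group_by!r}")
    rows = []
    for group, sub in profiles.groupby(group_by, sort=True):
        row: dict[str, object] = {group_by: group, "n": len(sub)}
        for g in genes:
            vals = sub[f"{g}_mean"].dropna().to_numpy(dtype=float)
            row[f"{g}_mean"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"{g}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Sample-size-weighted recombination of subgroup means."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != ns.shape or not len(means):
        raise ValueError("means and ns must be equal-length, non-empty")
    return float(np.sum(means * ns) / np.sum(ns))
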