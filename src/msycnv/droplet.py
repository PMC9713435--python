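"""Poisson quantification of duplex droplet-digital-PCR (ddPCR) wells.

A ddPCR well partitions a DNA sample into ~10^4 nanolitre droplets, each
scored positive or negative per fluorescence channel.  Under Poisson
partitioning the mean template copies per droplet is

    lambda = -ln(n_neg / n_total)

and the target copy number follows from the target:reference concentration
ratio times the reference copy number (2 for an autosomal reference gene).
The droplet partition volume cancels in the ratio, so copy-number calls are
invariant to it; it only matters when reporting absolute concentrations.

Confidence bounds on lambda use the delta method on the negative-droplet
fraction; bounds on the copy number propagate both channels' uncertainty via
the delta method on log(cn), treating the channels as independent Poisson
draws (cross-channel covariance is not estimable from stored counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Flag, auto
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical gene (assay) order used throughout reports.
GENES = ("ETSTY1", "ETSTY2", "ETSTY5", "HSFY", "RBMY", "SRY", "TSPY", "UBA1Y")

#: Events-per-well threshold below which droplet generation is deemed poor.
LOW_DROPLET_THRESHOLD = 8000

#: A well is flagged when its 95% CN interval is wider than this many copies.
HIGH_SE_CN_WIDTH = 1.0


class QCFlag(Flag):
    """Per-well quality flags; additive."""

    NONE = 0
    HIGH_SE = auto()
    LOW_DROPLETS = auto()
    SATURATED = auto()
    NO_REFERENCE = auto()

    def labels(self) -> str:
        """Serialize to a stable ``|``-joined string (empty when clean)."""
        return "|".join(f.name for f in QCFlag if f is not QCFlag.NONE and f in self)


def parse_flags(text: object) -> QCFlag:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return QCFlag.NONE
    flags = QCFlag.NONE
    for token in str(text).split("|"):
        token = token.strip()
        if token:
            flags |= QCFlag[token]
    return flags


class SaturatedWellError(ValueError):
    """All droplets positive: lambda is unbounded and the well is unusable."""


class EmptyWellError(ValueError):
    """A well with zero accepted droplets carries no information."""


@dataclass(frozen=True)
class WellCount:
    """Raw droplet counts for one duplex well (one target + one reference)."""

    sample_id: str
    assay_id: str
    n_total: int
    n_pos_target: int
    n_pos_ref: int

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ValueError(f"n_total must be >= 0, got {self.n_total}")
        for name in ("n_pos_target", "n_pos_ref"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_total:
                raise ValueError(
                    f"{name}={v} outside [0, n_total={self.n_total}] "
                    f"for {self.sample_id}/{self.assay_id}"
                )


@dataclass(frozen=True)
class AssayDef:
    """Assay configuration: target gene, autosomal reference, droplet volume.

    ``droplet_volume_nl`` defaults to the published QX200 partition volume;
    it affects concentration reporting only, never copy number.
    """

    gene: str
    reference_gene: str = "MYOZ1"
    reference_cn: int = 2
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.reference_cn < 1:
            raise ValueError("reference_cn must be >= 1")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be > 0")


@dataclass(frozen=True)
class PoissonEstimate:
    """Mean copies per droplet with delta-method confidence bounds."""

    lam: float
    lam_lo: float
    lam_hi: float
    sd: float
    n_total: int

    def __post_init__(self) -> None:
        if self.lam < 0 or not self.lam_lo <= self.lam <= self.lam_hi:
            raise ValueError("require 0 <= lam_lo <= lam <= lam_hi")


@dataclass(frozen=True)
class CNEstimate:
    """Copy number with 95% Poisson bounds and QC flags."""

    cn: float
    cn_min: float
    cn_max: float
    flags: QCFlag = QCFlag.NONE

    def __post_init__(self) -> None:
        if math.isnan(self.cn):
            return  # failed well (NO_REFERENCE); bounds undefined
        if self.cn < 0 or not self.cn_min <= self.cn <= self.cn_max:
            raise ValueError("require 0 <= cn_min <= cn <= cn_max")

    @property
    def ci_width(self) -> float:
        return self.cn_max - self.cn_min

    @property
    def passed(self) -> bool:
        return self.flags is QCFlag.NONE and not math.isnan(self.cn)


def lambda_estimate(n_neg: int, n_total: int, confidence: float = 0.95) -> PoissonEstimate:
    """Estimate mean copies per droplet from the negative-droplet count.

    lam = -ln(n_neg/n_total); sd(lam) = sqrt((1-p0)/(n_total*p0)) with
    p0 = n_neg/n_total (delta method on the binomial fraction).  Bounds are
    lam -/+ z*sd, clipped at zero.

    Raises
    ------
    EmptyWellError
        when ``n_total`` is zero.
    SaturatedWellError
        when no droplet is negative (lambda unbounded above).
    """
    if n_total <= 0:
        raise EmptyWellError("well has no accepted droplets")
    if not 0 <= n_neg <= n_total:
        raise ValueError(f"n_neg={n_neg} outside [0, {n_total}]")
    if n_neg == 0:
        raise SaturatedWellError(
            f"all {n_total} droplets positive; dilute and re-run the well"
        )
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    p0 = n_neg / n_total
    lam = -math.log(p0)
    sd = math.sqrt((1.0 - p0) / (n_total * p0))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return PoissonEstimate(
        lam=lam,
        lam_lo=max(lam - z * sd, 0.0),
        lam_hi=lam + z * sd,
        sd=sd,
        n_total=n_total,
    )


def concentration(est: PoissonEstimate, assay: AssayDef) -> float:
    """Absolute concentration in copies per microlitre of partitioned mix."""
    return est.lam / (assay.droplet_volume_nl * 1e-3)


def copy_number(
    target: PoissonEstimate,
    reference: PoissonEstimate,
    assay: AssayDef,
    confidence: float = 0.95,
) -> CNEstimate:
    """Target copy number from the duplex concentration ratio.

    cn = reference_cn * lambda_t / lambda_r.  The 95% interval propagates
    both channel uncertainties via the delta method on log(cn), assuming
    independent channels.  A zero reference lambda marks a failed well
    (NO_REFERENCE, cn undefined); a zero target lambda gives cn = 0 with a
    degenerate interval (no positive target droplets, e.g. female controls).
    """
    if reference.lam == 0:
        return CNEstimate(math.nan, math.nan, math.nan, QCFlag.NO_REFERENCE)
    cn = assay.reference_cn * target.lam / reference.lam
    if target.lam == 0:
        return CNEstimate(0.0, 0.0, 0.0)
    sd_log = math.sqrt(
        (target.sd / target.lam) ** 2 + (reference.sd / reference.lam) ** 2
    )
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return CNEstimate(cn, cn * math.exp(-z * sd_log), cn * math.exp(z * sd_log))


def qc_evaluate(cn: CNEstimate, well: WellCount) -> CNEstimate:
    """Apply the per-well QC rules, returning a flag-updated estimate.

    HIGH_SE when the 95% CN interval is wider than one copy; LOW_DROPLETS
    when fewer than 8,000 events were accepted.  Flags are additive on top
    of any already present.
    """
    flags = cn.flags
    if not math.isnan(cn.cn) and cn.ci_width > HIGH_SE_CN_WIDTH:
        flags |= QCFlag.HIGH_SE
    if well.n_total < LOW_DROPLET_THRESHOLD:
        flags |= QCFlag.LOW_DROPLETS
    return replace(cn, flags=flags)


def quantify_well(
    well: WellCount, assay: AssayDef, confidence: float = 0.95
) -> dict[str, object]:
    """Quantify a single duplex well; returns one tidy output row.

    Saturated channels are reported as failed rows (SATURATED flag, NaN
    estimates) rather than raised, so a whole plate can be processed and the
    failures surfaced in the output table.
    """
    row: dict[str, object] = {
        "sample_id": well.sample_id,
        "assay_id": well.assay_id,
        "lambda_t": math.nan,
        "lambda_r": math.nan,
        "conc_t": math.nan,
        "conc_r": math.nan,
        "cn": math.nan,
        "cn_min": math.nan,
        "cn_max": math.nan,
    }
    try:
        lam_t = lambda_estimate(well.n_total - well.n_pos_target, well.n_total, confidence)
        lam_r = lambda_estimate(well.n_total - well.n_pos_ref, well.n_total, confidence)
    except SaturatedWellError:
        est = qc_evaluate(
            CNEstimate(math.nan, math.nan, math.nan, QCFlag.SATURATED), well
        )
        row["flags"] = est.flags.labels()
        return row
    est = qc_evaluate(copy_number(lam_t, lam_r, assay, confidence), well)
    row.update(
        lambda_t=lam_t.lam,
        lambda_r=lam_r.lam,
        conc_t=concentration(lam_t, assay),
        conc_r=concentration(lam_r, assay),
        cn=est.cn,
        cn_min=est.cn_min,
        cn_max=est.cn_max,
        flags=est.flags.labels(),
    )
    return row


def quantify_table(
    wells: pd.DataFrame,
    assays: Mapping[str, AssayDef] | None = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Quantify a wells table (one duplex well per row).

    ``wells`` must carry columns ``sample_id, assay_id, n_total,
    n_pos_target, n_pos_ref``.  Unknown assay ids fall back to a default
    AssayDef with the assay id as gene name.
    """
    required = {"sample_id", "assay_id", "n_total", "n_pos_target", "n_pos_ref"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    assays = assays or {}
    rows = []
    for rec in wells.itertuples(index=False):
        well = WellCount(
            sample_id=str(rec.sample_id),
            assay_id=str(rec.assay_id),
            n_total=int(rec.n_total),
            n_pos_target=int(rec.n_pos_target),
            n_pos_ref=int(rec.n_pos_ref),
        )
        assay = assays.get(well.assay_id, AssayDef(gene=well.assay_id))
        rows.append(quantify_well(well, assay, confidence))
    return pd.DataFrame(rows)


def estimates_from_table(quant: pd.DataFrame) -> dict[tuple[str, str], list[CNEstimate]]:
    """Group a quantification table into CNEstimates per (sample, assay)."""
    out: dict[tuple[str, str], list[CNEstimate]] = {}
    for rec in quant.itertuples(index=False):
        est = CNEstimate(
            float(rec.cn), float(rec.cn_min), float(rec.cn_max),
            parse_flags(getattr(rec, "flags", "") or ""),
        )
        out.setdefault((str(rec.sample_id), str(rec.assay_id)), []).append(est)
    return out
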