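"""Nonallelic homologous recombination (NAHR) and CNV-dynamics simulators.

The horse Y carries its single-copy sex-determining gene SRY embedded
between nearly identical direct repeats, each bearing a copy of RBMY.
Because the male-specific Y never recombines with a homologue, double-
strand breaks are repaired against the sister chromatid; misalignment
between the distant identical repeats ("looping") produces an unequal
exchange whose reciprocal gametes carry a duplication (SRY x2, RBMY x3)
and a deletion (no SRY, single RBMY) — the deletion product is the
proposed origin of SRY-negative XY sex reversal.

Beyond the single-event mechanism, lineage and clone simulators model
per-meiosis (germline) and per-mitosis (somatic) copy-gain/loss dynamics
of multicopy genes across pedigrees and SCNT clone sets.  Haplotype labels
are invariant through every simulation by construction: CNV and SNV-based
haplotypes evolve by different mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class NahrEvent(str, Enum):
    NONE = "NONE"
    DUPLICATION = "DUPLICATION"
    DELETION = "DELETION"


@dataclass(frozen=True)
class Unit:
    """One structural unit of the repeat region.

    ``family`` tags homology: two units with the same non-None family are
    near-identical repeats that can misalign.  ``genes`` are the gene copies
    the unit carries.
    """

    family: str | None
    genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class RepeatRegion:
    """Ordered unit layout of one chromatid (sister chromatids identical)."""

    units: tuple[Unit, ...]

    def gene_count(self, gene: str) -> int:
        return sum(u.genes.count(gene) for u in self.units)

    def homologous_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i < j) of misalignable identical repeats."""
        return [
            (i, j)
            for i in range(len(self.units))
            for j in range(i + 1, len(self.units))
            if self.units[i].family is not None
            and self.units[i].family == self.units[j].family
        ]


#: SRY region layout: two RBMY-bearing direct repeats flanking single-copy SRY.
DEFAULT_SRY_REGION = RepeatRegion((
    Unit("direct_repeat", ("RBMY",)),
    Unit(None, ("SRY",)),
    Unit("direct_repeat", ("RBMY",)),
))


@dataclass(frozen=True)
class GameteProfile:
    sry_cn: int
    rbmy_cn: int
    event: NahrEvent

    def __post_init__(self) -> None:
        if self.sry_cn < 0 or self.rbmy_cn < 0:
            raise ValueError("copy numbers must be >= 0")


def simulate_nahr_event(
    region: RepeatRegion, rng: np.random.Generator
) -> tuple[GameteProfile, GameteProfile]:
    """One misaligned inter-sister exchange between distant identical repeats.

    The crossover joins repeat ``i`` of one chromatid to repeat ``j > i`` of
    its sister (pair chosen uniformly), yielding reciprocal products: a
    duplication chromatid carrying the i..j segment twice and a deletion
    chromatid lacking it.  Total copy number over the two gametes is exactly
    conserved.  A region without two misalignable repeats is a no-op (both
    gametes normal).
    """
    pairs = region.homologous_pairs()
    counts = (region.gene_count("SRY"), region.gene_count("RBMY"))
    if not pairs:
        normal = GameteProfile(*counts, NahrEvent.NONE)
        return normal, normal
    i, j = pairs[rng.integers(len(pairs))]
    dup = RepeatRegion(region.units[: j + 1] + region.units[i + 1:])
    dele = RepeatRegion(region.units[: i + 1] + region.units[j + 1:])
    return (
        GameteProfile(dup.gene_count("SRY"), dup.gene_count("RBMY"), NahrEvent.DUPLICATION),
        GameteProfile(dele.gene_count("SRY"), dele.gene_count("RBMY"), NahrEvent.DELETION),
    )


@dataclass(frozen=True)
class CnvRates:
    """Per-transmission gain/loss probabilities for one gene."""

    gain: float
    loss: float

    def __post_init__(self) -> None:
        if not (0 <= self.gain <= 1 and 0 <= self.loss <= 1 and self.gain + self.loss <= 1):
            raise ValueError("rates must lie in [0,1] with gain + loss <= 1")


#: Demonstration defaults chosen to show pedigree/clone-scale variability;
#: free parameters, not estimates of real per-meiosis rates.
DEFAULT_MEIOTIC_RATE = CnvRates(gain=0.025, loss=0.025)
DEFAULT_SOMATIC_RATE = CnvRates(gain=0.01, loss=0.01)


@dataclass
class CnTrajectory:
    """Copy numbers along a chain or star of individuals, plus an event log."""

    lineage_id: str
    records: list[dict] = field(default_factory=list)  # node, relation, gene, cn
    events: list[dict] = field(default_factory=list)   # node, gene, delta, origin

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events,
                            columns=["node", "gene", "delta", "origin"])


def _normalize_rates(
    rates: Mapping[str, CnvRates] | CnvRates | float, genes: Sequence[str]
) -> dict[str, CnvRates]:
    if isinstance(rates, Mapping):
        return {g: rates.get(g, CnvRates(0.0, 0.0)) for g in genes}
    if isinstance(rates, CnvRates):
        return {g: rates for g in genes}
    r = float(rates)
    return {g: CnvRates(r / 2, r / 2) for g in genes}


def _transmit(
    cns: dict[str, int],
    rates: Mapping[str, CnvRates],
    rng: np.random.Generator,
    node: str,
    origin: str,
    events: list[dict],
    step: int = 1,
    cn_proportional: bool = False,
) -> dict[str, int]:
    """One transmission: per-gene independent gain/loss events.

    In CN-proportional mode the event probabilities scale with the current
    copy number (capped so gain+loss <= 1), reflecting the higher
    rearrangement exposure of larger amplicon arrays.
    """
    out = dict(cns)
    for gene, cn in cns.items():
        r = rates[gene]
        gain, loss = r.gain, r.loss
        if cn_proportional:
            scale = max(cn, 0)
            gain, loss = gain * scale, loss * scale
            tot = gain + loss
            if tot > 1.0:
                gain, loss = gain / tot, loss / tot
        u = rng.random()
        delta = 0
        if u < gain:
            delta = step
        elif u < gain + loss:
            delta = -step
        if delta:
            new = cn + delta
            if new < 0:
                delta = -cn  # loss clipped at zero, logged as the realized change
                new = 0
            if delta:
                out[gene] = new
                events.append({"node": node, "gene": gene,
                               "delta": int(delta), "origin": origin})
    return out


def simulate_lineage(
    founder: Mapping[str, int],
    n_generations: int,
    rates: Mapping[str, CnvRates] | CnvRates | float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    step: int = 1,
    cn_proportional: bool = False,
    lineage_id: str = "lineage",
    founder_ht: str | None = None,
) -> CnTrajectory:
    """Transmit a founder CN vector through successive meioses.

    Each generation applies independent per-gene gain/loss events; losses
    never take a copy number below zero (clipped, logged).  With all rates
    zero the trajectory is constant.  Multi-copy jumps (e.g. a 6-copy
    transgenerational loss) arise from repeated single-step events or a
    larger configured ``step``.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    genes = list(founder)
    rmap = _normalize_rates(rates, genes)
    cns = {g: int(founder[g]) for g in genes}
    if any(v < 0 for v in cns.values()):
        raise ValueError("founder copy numbers must be >= 0")
    traj = CnTrajectory(lineage_id)

    def record(node: str, relation: str, vec: Mapping[str, int]) -> None:
        for g in genes:
            traj.records.append({
                "lineage_id": lineage_id, "node": node, "relation": relation,
                "gene": g, "cn": int(vec[g]),
                **({"ht": founder_ht} if founder_ht is not None else {}),
            })

    record("G0", "founder", cns)
    for gen in range(1, n_generations + 1):
        node = f"G{gen}"
        cns = _transmit(cns, rmap, rng, node, "germline", traj.events,
                        step=step, cn_proportional=cn_proportional)
        record(node, "descendant", cns)
    return traj


def simulate_clones(
    donor: Mapping[str, int],
    n_clones: int,
    somatic_rates: Mapping[str, CnvRates] | CnvRates | float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    step: int = 1,
    n_mitoses: int = 1,
    lineage_id: str = "clone_set",
    donor_ht: str | None = None,
) -> CnTrajectory:
    """Draw SCNT clones independently from a donor with somatic perturbation.

    Each clone undergoes ``n_mitoses`` rounds of per-gene somatic gain/loss
    from the donor vector.  With zero rates every clone equals the donor.
    Haplotype labels never change through cloning.
    """
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    genes = list(donor)
    rmap = _normalize_rates(somatic_rates, genes)
    base = {g: int(donor[g]) for g in genes}
    traj = CnTrajectory(lineage_id)
    for g in genes:
        traj.records.append({
            "lineage_id": lineage_id, "node": "donor", "relation": "donor",
            "gene": g, "cn": base[g],
            **({"ht": donor_ht} if donor_ht is not None else {}),
        })
    for c in range(1, n_clones + 1):
        node = f"clone{c}"
        vec = dict(base)
        for _ in range(n_mitoses):
            vec = _transmit(vec, rmap, rng, node, "somatic", traj.events, step=step)
        for g in genes:
            traj.records.append({
                "lineage_id": lineage_id, "node": node, "relation": "clone",
                "gene": g, "cn": int(vec[g]),
                **({"ht": donor_ht} if donor_ht is not None else {}),
            })
    return traj
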