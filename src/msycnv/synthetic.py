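"""Synthetic cohort, droplet-count and genotype generator.

Emulates the study design end to end so every pipeline stage is testable
without any raw-data download: breed-structured cohorts whose integer true
copy numbers are drawn from the bundled per-breed reference means/SDs,
duplex ddPCR wells whose positive-droplet counts follow binomial sampling
of the Poisson partition probabilities (reference lambda encodes the assay
dynamic range, target lambda = reference lambda * CN / 2), haplotype labels
drawn from the bundled survey frequencies, and tree-consistent marker
genotypes.  Abnormal classes (complete Y deletion, SRY-negative DSD,
SRY/RBMY amplification, a multi-gene high-CN outlier) override the relevant
genes exactly.  Everything is deterministic under the configured seed.

The per-breed SDs are treated as between-individual biological variation;
measurement noise enters only through droplet sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .droplet import GENES
from .haplotree import BackboneTree, next_markers
from . import reference

#: Abnormal-class labels understood by the generator and the classifier.
ABNORMAL_CLASSES = (
    "Y_DELETION", "SRY_NEG_DSD", "SRY_RBMY_AMPLIFIED", "MULTI_GENE_OUTLIER",
)

#: Class mix mirroring the study's abnormal cohort proportions
#: (4 Y-deletions, 12 SRY-negative DSD, 21 amplified, 1 outlier of ~282).
STUDY_ABNORMAL_FRACTIONS = {
    "Y_DELETION": 4 / 282,
    "SRY_NEG_DSD": 12 / 282,
    "SRY_RBMY_AMPLIFIED": 21 / 282,
    "MULTI_GENE_OUTLIER": 1 / 282,
}


@dataclass(frozen=True)
class BreedSpec:
    name: str
    n: int
    cn_mean: Mapping[str, float]
    cn_sd: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")


@dataclass
class PopulationConfig:
    """Study conditions for one synthetic cohort; ``seed`` is mandatory."""

    breeds: Sequence[BreedSpec]
    seed: int
    ht_counts: Mapping[str, int] = field(default_factory=dict)
    abnormal_fractions: Mapping[str, float] = field(default_factory=dict)
    wells_per_sample: int = 2
    droplet_mean: float = 15_000.0
    droplet_sd: float = 1_500.0
    droplet_floor: int = 1_000
    low_droplet_rate: float = 0.0
    reference_lambda: float = 0.3
    genes: Sequence[str] = GENES

    def __post_init__(self) -> None:
        bad = set(self.abnormal_fractions) - set(ABNORMAL_CLASSES)
        if bad:
            raise ValueError(f"unknown abnormal classes: {sorted(bad)}")
        total = sum(self.abnormal_fractions.values())
        if any(f < 0 for f in self.abnormal_fractions.values()) or total > 1:
            raise ValueError("abnormal fractions must be >= 0 and sum <= 1")
        if self.reference_lambda <= 0:
            raise ValueError("reference_lambda must be > 0")
        if self.wells_per_sample < 1:
            raise ValueError("wells_per_sample must be >= 1")


def default_population_config(
    seed: int, include_abnormal: bool = False
) -> PopulationConfig:
    """The bundled study conditions: 209 horses of 22 breeds, survey HT mix."""
    ref = reference.load_breed_reference()
    breeds = []
    for rec in ref.itertuples(index=False):
        means = {g: float(getattr(rec, f"{g}_mean")) for g in GENES}
        sds = {}
        for g in GENES:
            sd = getattr(rec, f"{g}_sd")
            sds[g] = 0.0 if pd.isna(sd) else float(sd)
        breeds.append(BreedSpec(str(rec.breed), int(rec.n), means, sds))
    ht = {
        str(r.node): int(r.count)
        for r in reference.load_ht_counts().itertuples(index=False)
        if int(r.count) > 0
    }
    return PopulationConfig(
        breeds=breeds,
        seed=seed,
        ht_counts=ht,
        abnormal_fractions=dict(STUDY_ABNORMAL_FRACTIONS) if include_abnormal else {},
    )


def _apply_class(cls: str, cns: dict[str, int], rng: np.random.Generator) -> dict[str, int]:
    out = dict(cns)
    if cls == "Y_DELETION":
        return {g: 0 for g in out}
    if cls == "SRY_NEG_DSD":
        out["SRY"] = 0
        out["RBMY"] = 1
        return out
    if cls == "SRY_RBMY_AMPLIFIED":
        out["SRY"] = int(rng.choice([2, 3]))
        out["RBMY"] = int(rng.choice([1, 3]))
        return out
    if cls == "MULTI_GENE_OUTLIER":
        # TR028-like: most genes far above cohort level, RBMY a single copy
        for g in out:
            if g not in ("RBMY", "SRY"):
                out[g] = max(out[g] * 3, out[g] + 6)
        out["SRY"] = 3
        out["RBMY"] = 1
        return out
    raise ValueError(f"unknown class {cls!r}")


def generate_population(cfg: PopulationConfig) -> pd.DataFrame:
    """Sample table with breed, cohort, haplotype and true integer CNs.

    True CNs are per-breed normal draws rounded to integers and clamped at
    zero; abnormal classes then override the relevant genes exactly.
    Haplotypes are drawn from the configured count vector (uniform over the
    backbone's survey frequencies, independent of breed).
    """
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.abnormal_fractions)
    probs = np.array([cfg.abnormal_fractions[c] for c in classes], dtype=float)
    ht_labels = list(cfg.ht_counts) or [None]
    ht_weights = np.array(
        [cfg.ht_counts[h] for h in cfg.ht_counts] or [1], dtype=float
    )
    ht_weights = ht_weights / ht_weights.sum()
    rows = []
    idx = 0
    for breed in cfg.breeds:
        for _ in range(breed.n):
            idx += 1
            cns = {}
            for g in cfg.genes:
                draw = rng.normal(breed.cn_mean.get(g, 0.0), breed.cn_sd.get(g, 0.0))
                cns[g] = max(int(np.floor(draw + 0.5)), 0)
            u = rng.random()
            cohort = "normal"
            acc = 0.0
            for c, p in zip(classes, probs):
                acc += p
                if u < acc:
                    cohort = c
                    cns = _apply_class(c, cns, rng)
                    break
            ht = ht_labels[rng.choice(len(ht_labels), p=ht_weights)] if ht_labels[0] else ""
            rows.append({
                "sample_id": f"S{idx:04d}", "breed": breed.name,
                "cohort": cohort, "ht": ht,
                **{g: cns[g] for g in cfg.genes},
            })
    return pd.DataFrame(rows)


def simulate_wells_for_cn(
    true_cn: float,
    n_wells: int,
    rng: np.random.Generator,
    n_droplets: int = 15_000,
    reference_lambda: float = 0.3,
    reference_cn: int = 2,
    sample_id: str = "S0001",
    assay_id: str = "TSPY",
) -> pd.DataFrame:
    """Duplex replicate wells for one (possibly non-integer) true copy number.

    Positives are binomial draws of the Poisson occupancy probabilities:
    reference ~ B(n, 1 - exp(-lambda_r)), target ~ B(n, 1 - exp(-lambda_r *
    CN / reference_cn)).
    """
    lam_r = reference_lambda
    lam_t = reference_lambda * true_cn / reference_cn
    rows = []
    for _ in range(n_wells):
        rows.append({
            "sample_id": sample_id,
            "assay_id": assay_id,
            "n_total": int(n_droplets),
            "n_pos_target": int(rng.binomial(n_droplets, 1.0 - np.exp(-lam_t))),
            "n_pos_ref": int(rng.binomial(n_droplets, 1.0 - np.exp(-lam_r))),
        })
    return pd.DataFrame(rows)


def generate_droplet_data(samples: pd.DataFrame, cfg: PopulationConfig) -> pd.DataFrame:
    """Well-count table for every sample x gene x replicate.

    Droplet totals are normal draws (floored); a configured fraction of
    wells is injected below the 8,000-event threshold to exercise QC.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lam_r = cfg.reference_lambda
    rows = []
    for rec in samples.itertuples(index=False):
        for g in cfg.genes:
            cn = float(getattr(rec, g))
            lam_t = lam_r * cn / 2.0
            for _ in range(cfg.wells_per_sample):
                if cfg.low_droplet_rate and rng.random() < cfg.low_droplet_rate:
                    n_total = int(rng.integers(3_000, 8_000))
                else:
                    n_total = int(max(rng.normal(cfg.droplet_mean, cfg.droplet_sd),
                                      cfg.droplet_floor))
                rows.append({
                    "sample_id": rec.sample_id,
                    "assay_id": g,
                    "n_total": n_total,
                    "n_pos_target": int(rng.binomial(n_total, 1.0 - np.exp(-lam_t))),
                    "n_pos_ref": int(rng.binomial(n_total, 1.0 - np.exp(-lam_r))),
                })
    return pd.DataFrame(rows)


def _protocol_tested_markers(tree: BackboneTree, node: str) -> set[str]:
    """Markers the sequential protocol types en route to ``node``.

    At every node on the root path the protocol queries all child-edge
    markers before following the derived edge, so siblings' markers are
    typed (and come back ancestral) while everything deeper stays untested.
    """
    tested: set[str] = set()
    for n in tree.path_to(node):
        tested.update(next_markers(tree, n))
    if tree.gate_marker:
        tested.add(tree.gate_marker)
    return tested


def generate_genotypes(
    samples: pd.DataFrame,
    tree: BackboneTree,
    missing_rate: float = 0.0,
    mode: str = "path",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format marker calls consistent with each sample's haplotype.

    Derived alleles fall exactly on the root->HT path; everything off-path
    is ancestral.  ``mode="path"`` drops (with probability ``missing_rate``)
    only markers the sequential protocol would not have typed anyway;
    ``mode="uniform"`` is a stress mode dropping any marker, gate included.
    """
    if mode not in ("path", "uniform"):
        raise ValueError(f"unknown missingness mode {mode!r}")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    for rec in samples.itertuples(index=False):
        ht = str(rec.ht)
        if ht not in tree.nodes:
            raise KeyError(f"sample {rec.sample_id}: haplotype {ht!r} not in tree")
        on_path = tree.path_markers(ht)
        droppable = (
            {m.name for m in tree.markers}
            if mode == "uniform"
            else {m.name for m in tree.markers} - _protocol_tested_markers(tree, ht)
        )
        for m in tree.markers:
            if missing_rate and m.name in droppable and rng.random() < missing_rate:
                continue
            allele = m.derived if m.name in on_path else m.ancestral
            rows.append({"sample_id": rec.sample_id, "marker": m.name, "allele": allele})
    return pd.DataFrame(rows, columns=["sample_id", "marker", "allele"])


def generate_all(
    cfg: PopulationConfig, tree: BackboneTree | None = None
) -> dict[str, pd.DataFrame]:
    """Full synthetic input set: truth, wells, metadata, genotypes."""
    truth = generate_population(cfg)
    wells = generate_droplet_data(truth, cfg)
    metadata = truth[["sample_id", "breed", "cohort"]].copy()
    out = {"truth": truth, "wells": wells, "metadata": metadata}
    if tree is not None:
        if not cfg.ht_counts:
            raise ValueError(
                "config has no ht_counts; cannot generate tree-consistent genotypes"
            )
        out["genotypes"] = generate_genotypes(truth, tree, seed=cfg.seed + 2)
    return out
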