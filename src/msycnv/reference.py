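"""Bundled reference tables: published cohort summaries used as generator
seeds and as worked-example inputs.

The package ships per-breed copy-number means/SDs for the 8 assayed genes
in a 209-horse multibreed survey cohort, the individuals with deviant
SRY/RBMY copy number, cryptorchid-cohort group means, a related-males CN
table (pedigrees and SCNT clone sets), and the haplotype counts of the
survey cohort on the condensed backbone.  All live as plain CSV under
``msycnv/data``.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .droplet import GENES


def _read(name: str) -> pd.DataFrame:
    with (files("msycnv.data") / name).open("r") as fh:
        return pd.read_csv(fh)


def load_breed_reference() -> pd.DataFrame:
    """Per-breed CN mean/SD table: breed, n, <gene>_mean, <gene>_sd."""
    return _read("breed_cn_reference.csv")


def load_sry_rbmy_deviants() -> pd.DataFrame:
    """Individuals with SRY CN deviating from the single-copy norm."""
    return _read("sry_rbmy_deviants.csv")


def load_cryptorchid_groups() -> pd.DataFrame:
    """Cryptorchid vs normal Quarter Horse cohort mean CN table."""
    return _read("cryptorchid_group_means.csv")


def load_related_males() -> pd.DataFrame:
    """Pedigree and SCNT clone-set CN table (NaN where DNA was exhausted)."""
    return _read("related_males_cn.csv")


def load_ht_counts() -> pd.DataFrame:
    """Survey-cohort haplotype counts per backbone node (zero rows kept)."""
    return _read("ht_counts.csv")


def breed_cn_range(gene: str) -> float:
    """Max minus min per-breed mean CN for one gene across the breed table."""
    if gene not in GENES:
        raise KeyError(f"unknown gene {gene!r}")
    col = f"{gene}_mean"
    vals = load_breed_reference()[col]
    return float(vals.max() - vals.min())
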