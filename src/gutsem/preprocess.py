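"""Upstream preparation of microbiome and phenotype data.

Turns raw OTU count tables and weekly body-weight records into the
analysis-ready variables of the causal model: prevalence/abundance
filtering of OTUs, cumulative-sum-scaling (CSS) normalization, average
daily gain (ADG) as a within-animal regression slope, and the join of
one OTU's normalized abundance with the growth phenotypes, covariates
and the genomic relationship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sem_core import SemDataset

__all__ = [
    "OtuCountTable",
    "NormalizedOtuTable",
    "BodyWeightSeries",
    "PhenotypeTable",
    "filter_otus",
    "css_normalize",
    "compute_adg",
    "assemble_sem_dataset",
    "read_otu_table_tsv",
    "read_otu_table_biom",
    "read_taxonomy_tsv",
    "read_body_weights_tsv",
    "read_phenotypes_tsv",
]


@dataclass
class OtuCountTable:
    """Raw OTU counts, samples x OTUs, with optional taxonomy strings.

    Counts must be non-negative integers; sample and OTU identifiers must
    be unique; taxonomy is keyed by a subset of the OTU ids and uses
    rank-prefixed strings (``k__;p__;...``), possibly "Unassigned".
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if self.counts.size and (
            np.any(self.counts < 0) or not np.allclose(self.counts, np.round(self.counts))
        ):
            raise ValueError("counts must be non-negative integers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("otu_ids must be unique")
        unknown = set(self.taxonomy) - set(self.otu_ids)
        if unknown:
            raise ValueError(f"taxonomy keys not in otu_ids: {sorted(unknown)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)


@dataclass
class NormalizedOtuTable:
    """CSS-normalized OTU abundances with per-sample scaling factors."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    scaling_factors: np.ndarray
    reference_scale: float
    log2_transformed: bool = False
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scaling_factors = np.asarray(self.scaling_factors, dtype=float)
        if self.scaling_factors.shape != (len(self.sample_ids),):
            raise ValueError("one scaling factor per sample required")
        if np.any(self.scaling_factors <= 0) or self.reference_scale <= 0:
            raise ValueError("scaling factors and reference scale must be positive")
        if np.any(self.values < 0):
            # CSS output is non-negative by construction; other continuous
            # abundance scales (e.g. simulated traits) are tolerated
            warnings.warn(
                "normalized table contains negative values: not a CSS scale",
                stacklevel=2,
            )

    def otu_values(self, otu_id: str) -> np.ndarray:
        j = self.otu_ids.index(otu_id)
        return self.values[:, j]


@dataclass
class BodyWeightSeries:
    """Weekly body-weight records for one animal: (age in days, weight in g)."""

    animal_id: str
    observations: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for age, weight in self.observations:
            if age <= 0 or weight <= 0:
                raise ValueError(f"{self.animal_id}: ages and weights must be positive")


@dataclass
class PhenotypeTable:
    """Per-animal phenotype and covariate records.

    ``regime`` determines which ADG slot is observed: animals fed ad
    libitum carry ``adg_al`` and have ``adg_r`` missing, and vice versa.
    """

    frame: pd.DataFrame

    REQUIRED = ("animal_id", "regime", "adg", "batch_farm", "ww_class", "litter_id", "cage_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        bad = set(self.frame["regime"]) - {"AL", "R"}
        if bad:
            raise ValueError(f"regime must be 'AL' or 'R', got {sorted(bad)}")
        if self.frame["litter_id"].isna().any() or self.frame["cage_id"].isna().any():
            raise ValueError("litter_id and cage_id must be non-missing")
        if self.frame["animal_id"].duplicated().any():
            raise ValueError("duplicate animal_id in phenotype table")
        # design intent: at most two litter-mates share a cage
        per = self.frame.groupby(["litter_id", "cage_id"]).size()
        if (per > 2).any():
            warnings.warn(
                "some litters contribute more than 2 animals to one cage "
                "(litter and maternal effects may confound)",
                stacklevel=2,
            )


def filter_otus(
    table: OtuCountTable,
    prevalence_min: float = 0.05,
    abundance_min: float = 0.0001,
) -> OtuCountTable:
    """Discard rare OTUs by prevalence and relative total abundance.

    An OTU is retained when it is detected (count > 0) in at least
    ``prevalence_min`` of the samples AND its total count is at least
    ``abundance_min`` of the grand total over the whole table. Values
    exactly at a threshold are retained (the removal rule is strictly
    "less than"). Column order is preserved; samples are untouched.
    """
    if not 0 <= prevalence_min <= 1 or not 0 <= abundance_min <= 1:
        raise ValueError("thresholds must be fractions in [0, 1]")
    if table.n_samples == 0 or table.n_otus == 0:
        raise ValueError("cannot filter an empty OTU table")
    counts = table.counts
    prevalence = np.count_nonzero(counts > 0, axis=0) / table.n_samples
    grand_total = counts.sum()
    if grand_total == 0:
        raise ValueError("OTU table contains no counts")
    rel_abundance = counts.sum(axis=0) / grand_total
    keep = (prevalence >= prevalence_min) & (rel_abundance >= abundance_min)
    if not keep.any():
        raise ValueError(
            "all OTUs removed: "
            f"{int((prevalence < prevalence_min).sum())} below prevalence "
            f"{prevalence_min}, {int((rel_abundance < abundance_min).sum())} below "
            f"relative abundance {abundance_min}"
        )
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return OtuCountTable(
        sample_ids=list(table.sample_ids),
        otu_ids=kept_ids,
        counts=counts[:, keep],
        taxonomy={o: t for o, t in table.taxonomy.items() if o in set(kept_ids)},
    )


def css_normalize(
    table: OtuCountTable,
    quantile: float = 0.5,
    log2_transform: bool = False,
    reference_scale: float | None = None,
) -> NormalizedOtuTable:
    """Cumulative sum scaling: divide each sample by the cumulative count sum
    up to a quantile of its positive-count distribution.

    For sample *i* the scaling factor is the sum of the counts that are at
    most the ``quantile``-level count among that sample's positive counts.
    Values are then ``counts / s_i * reference_scale`` where the reference
    scale defaults to the median scaling factor across samples (keeping the
    output on a count-like scale). With ``log2_transform`` the result is
    ``log2(value + 1)``.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie strictly between 0 and 1")
    counts = np.asarray(table.counts, dtype=float)
    factors = np.empty(table.n_samples)
    for i, row in enumerate(counts):
        positive = row[row > 0]
        if positive.size == 0:
            raise ValueError(f"sample {table.sample_ids[i]!r} has zero total count")
        threshold = np.quantile(positive, quantile)
        s = row[row <= threshold].sum()
        if s <= 0:
            raise ValueError(f"sample {table.sample_ids[i]!r} has zero CSS scaling factor")
        factors[i] = s
    ref = float(np.median(factors)) if reference_scale is None else float(reference_scale)
    values = counts / factors[:, None] * ref
    if log2_transform:
        values = np.log2(values + 1.0)
    return NormalizedOtuTable(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        values=values,
        scaling_factors=factors,
        reference_scale=ref,
        log2_transformed=log2_transform,
        taxonomy=dict(table.taxonomy),
    )


def compute_adg(series: BodyWeightSeries) -> float:
    """Average daily gain (g/day): OLS slope of body weight on age."""
    obs = series.observations
    if len(obs) < 2:
        raise ValueError(f"{series.animal_id}: need at least 2 body-weight records")
    ages = np.array([a for a, _ in obs], dtype=float)
    weights = np.array([w for _, w in obs], dtype=float)
    if np.unique(ages).size < 2:
        raise ValueError(f"{series.animal_id}: need at least 2 distinct ages")
    x = ages - ages.mean()
    return float(x @ (weights - weights.mean()) / (x @ x))


def assemble_sem_dataset(
    phenotypes: PhenotypeTable,
    norm_table: NormalizedOtuTable,
    otu_id: str,
    grm,
) -> SemDataset:
    """Join one OTU's normalized abundance with the growth phenotypes.

    Every phenotyped animal must have a microbiome sample and a genotype
    row; records are aligned to the GRM's animal ordering.
    """
    frame = phenotypes.frame
    pheno_ids = list(frame["animal_id"].astype(str))
    missing_micro = sorted(set(pheno_ids) - set(map(str, norm_table.sample_ids)))
    missing_geno = sorted(set(pheno_ids) - set(map(str, grm.animal_ids)))
    if missing_micro or missing_geno:
        raise ValueError(
            f"unmatched animal ids: no microbiome sample for {missing_micro[:10]}, "
            f"no genotype for {missing_geno[:10]}"
        )
    order = [a for a in map(str, grm.animal_ids) if a in set(pheno_ids)]
    if len(order) != len(pheno_ids):
        raise ValueError("phenotyped animals missing from GRM ordering")
    sub = frame.set_index(frame["animal_id"].astype(str)).loc[order]
    m_col = norm_table.otu_values(otu_id)
    m_by_sample = dict(zip(map(str, norm_table.sample_ids), m_col))
    y_m = np.array([m_by_sample[a] for a in order], dtype=float)

    is_al = (sub["regime"] == "AL").to_numpy()
    adg = sub["adg"].to_numpy(dtype=float)
    y_al = np.where(is_al, adg, np.nan)
    y_r = np.where(~is_al, adg, np.nan)

    grm_sub = grm.subset(order)
    return SemDataset(
        animal_ids=order,
        y_al=y_al,
        y_r=y_r,
        y_m=y_m,
        batch_farm=pd.Categorical(sub["batch_farm"]).codes.astype(int),
        ww_class=pd.Categorical(sub["ww_class"]).codes.astype(int),
        litter=pd.Categorical(sub["litter_id"]).codes.astype(int),
        cage=pd.Categorical(sub["cage_id"]).codes.astype(int),
        grm=grm_sub,
        otu_id=otu_id,
    )


# ---------------------------------------------------------------------------
# readers


def read_otu_table_tsv(
    path,
    orientation: str = "auto",
    taxonomy: dict[str, str] | None = None,
) -> OtuCountTable:
    """Read an OTU count table from TSV.

    ``orientation`` is one of ``"samples_by_otus"``, ``"otus_by_samples"``
    or ``"auto"`` (wider-than-tall tables with row labels that look like
    OTU ids are transposed so that rows are samples).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation == "auto":
        orientation = (
            "otus_by_samples" if df.shape[0] > df.shape[1] else "samples_by_otus"
        )
    if orientation == "otus_by_samples":
        df = df.T
    elif orientation != "samples_by_otus":
        raise ValueError(f"unknown orientation {orientation!r}")
    return OtuCountTable(
        sample_ids=list(map(str, df.index)),
        otu_ids=list(map(str, df.columns)),
        counts=df.to_numpy(),
        taxonomy=taxonomy or {},
    )


def read_otu_table_biom(path) -> OtuCountTable:
    """Read a BIOM 2.x (HDF5) OTU table.

    Observations (OTUs) are stored CSC-style along rows and samples along
    columns; taxonomy is picked up from ``observation/metadata/taxonomy``
    when present.
    """
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        otu_ids = [x.decode() for x in f["observation/ids"][:]]
        sample_ids = [x.decode() for x in f["sample/ids"][:]]
        mat = csr_matrix(
            (
                f["observation/matrix/data"][:],
                f["observation/matrix/indices"][:],
                f["observation/matrix/indptr"][:],
            ),
            shape=(len(otu_ids), len(sample_ids)),
        )
        taxonomy: dict[str, str] = {}
        if "observation/metadata/taxonomy" in f:
            tax = f["observation/metadata/taxonomy"][:]
            for otu, ranks in zip(otu_ids, tax):
                if ranks.ndim == 0:
                    taxonomy[otu] = ranks.decode()
                else:
                    taxonomy[otu] = ";".join(r.decode() for r in ranks)
    counts = np.asarray(mat.T.todense())
    return OtuCountTable(sample_ids, otu_ids, np.round(counts).astype(np.int64), taxonomy)


def read_taxonomy_tsv(path) -> dict[str, str]:
    """Two-column TSV: otu_id, rank-prefixed taxonomy string."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "taxonomy"], comment="#")
    return dict(zip(df["otu_id"].astype(str), df["taxonomy"].astype(str)))


def read_body_weights_tsv(path) -> list[BodyWeightSeries]:
    """Long-format TSV with columns animal_id, age_days, weight_g."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for animal, grp in df.groupby("animal_id", sort=False):
        obs = list(zip(grp["age_days"].astype(float), grp["weight_g"].astype(float)))
        out.append(BodyWeightSeries(str(animal), obs))
    return out


def read_phenotypes_tsv(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "litter_id": str, "cage_id": str})
    return PhenotypeTable(df)
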