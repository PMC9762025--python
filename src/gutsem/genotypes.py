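"""SNP quality control and genomic relationship matrix construction.

QC applies the standard four criteria sequentially (individual call
rate, then SNP call rate, minor allele frequency and autosomal status
computed on the retained individuals). The GRM follows VanRaden's first
method: columns of the dosage matrix are centered by twice the observed
allele frequency and the cross-product is scaled by 2*sum(p(1-p)). A
small identity blend keeps the matrix positive definite for use inside
the Gibbs sampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GenomicRelationshipMatrix",
    "snp_qc",
    "impute_missing",
    "compute_grm",
    "read_plink",
    "read_dosage_tsv",
    "write_grm_tsv",
    "read_grm_tsv",
]

_SEX_CHROMS = {"X", "Y", "XY", "MT", "M", "0"}


@dataclass
class GenotypeMatrix:
    """Minor-allele dosages in {0, 1, 2}, NaN for missing."""

    animal_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # animals x SNPs, float with NaN for missing
    snp_meta: pd.DataFrame | None = None  # columns: chromosome, position, is_autosomal

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id lists")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            # mean-imputed matrices carry fractional values; raw input must not
            if getattr(self, "_allow_fractional", False) is False and np.any(
                (vals < 0) | (vals > 2)
            ):
                raise ValueError("dosages must lie in [0, 2]")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("animal_ids must be unique")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class GenomicRelationshipMatrix:
    """Symmetric marker-based relationship matrix, identity-blended."""

    animal_ids: list[str]
    values: np.ndarray
    blend_weight: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square over animal_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    def subset(self, animal_ids: list[str]) -> "GenomicRelationshipMatrix":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([index[a] for a in animal_ids])
        return GenomicRelationshipMatrix(
            list(animal_ids), self.values[np.ix_(idx, idx)], self.blend_weight
        )


def snp_qc(
    g: GenotypeMatrix,
    ind_call_min: float = 0.90,
    snp_call_min: float = 0.95,
    maf_min: float = 0.05,
    autosomal_only: bool = True,
) -> GenotypeMatrix:
    """Filter individuals then SNPs.

    Individuals with call rate <= ``ind_call_min`` are removed first; then
    SNPs with call rate <= ``snp_call_min``, MAF <= ``maf_min`` (computed on
    the retained individuals, matching PLINK's sequential behavior) or a
    non-autosomal location are removed. Row/column order is preserved.
    """
    for t in (ind_call_min, snp_call_min, maf_min):
        if not 0 <= t <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    observed = ~np.isnan(g.dosages)
    ind_call = observed.mean(axis=1)
    keep_ind = ind_call > ind_call_min
    if not keep_ind.any():
        raise ValueError(
            f"all {g.n_animals} individuals removed at call rate > {ind_call_min}"
        )
    d = g.dosages[keep_ind]
    obs = observed[keep_ind]

    snp_call = obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    keep_snp = (snp_call > snp_call_min) & (maf > maf_min)
    n_call = int((snp_call <= snp_call_min).sum())
    n_maf = int((maf <= maf_min).sum())
    n_auto = 0
    if autosomal_only:
        if g.snp_meta is None or "is_autosomal" not in g.snp_meta.columns:
            raise ValueError("autosomal_only requires snp_meta with is_autosomal")
        auto = g.snp_meta["is_autosomal"].to_numpy(dtype=bool)
        n_auto = int((~auto).sum())
        keep_snp &= auto
    if not keep_snp.any():
        raise ValueError(
            f"all {g.n_snps} SNPs removed (call rate: {n_call}, MAF: {n_maf}, "
            f"non-autosomal: {n_auto})"
        )
    return GenotypeMatrix(
        animal_ids=[a for a, k in zip(g.animal_ids, keep_ind) if k],
        snp_ids=[s for s, k in zip(g.snp_ids, keep_snp) if k],
        dosages=d[:, keep_snp],
        snp_meta=None if g.snp_meta is None else g.snp_meta.loc[keep_snp].reset_index(drop=True),
    )


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the SNP mean (real-valued)."""
    d = g.dosages.copy()
    nan_mask = np.isnan(d)
    if not nan_mask.any():
        return g
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        bad = [s for s, m in zip(g.snp_ids, all_missing) if m]
        raise ValueError(f"SNPs with no observed genotypes cannot be imputed: {bad[:10]}")
    col_mean = np.nanmean(d, axis=0)
    d[nan_mask] = np.broadcast_to(col_mean, d.shape)[nan_mask]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.animal_ids = list(g.animal_ids)
    out.snp_ids = list(g.snp_ids)
    out.dosages = d
    out.snp_meta = g.snp_meta
    return out


def compute_grm(g: GenotypeMatrix, blend_weight: float = 0.01) -> GenomicRelationshipMatrix:
    """VanRaden method-1 GRM with an identity blend.

    W = dosages centered by 2*p_hat per SNP; G = W W' / (2 * sum p_hat(1-p_hat));
    the result is blend*I + (1-blend)*G, guaranteeing positive definiteness.
    """
    if g.n_snps < 2:
        raise ValueError("need at least 2 SNPs for a GRM")
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("impute missing dosages before computing the GRM")
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs are monomorphic: GRM denominator is zero")
    w = d - 2.0 * p
    grm = (w @ w.T) / denom
    if not 0 <= blend_weight < 1:
        raise ValueError("blend_weight must lie in [0, 1)")
    values = (1.0 - blend_weight) * grm + blend_weight * np.eye(g.n_animals)
    return GenomicRelationshipMatrix(list(g.animal_ids), values, blend_weight)


# ---------------------------------------------------------------------------
# io

# PLINK .bed 2-bit codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2.
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix, autosomes: set[str] | None = None) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triple (SNP-major .bed).

    Dosages count the A1 allele. ``autosomes`` names the chromosomes to
    flag as autosomal; by default any numeric chromosome code except 0 is
    treated as autosomal and X/Y/XY/MT as sex-linked.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chromosome", "snp_id", "cm", "position", "a1", "a2"], dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * m:
        raise ValueError("bed file size does not match fam/bim dimensions")
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit genotype codes, low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_DECODE[codes].T  # animals x SNPs

    chrom = bim["chromosome"].str.upper()
    if autosomes is not None:
        is_auto = chrom.isin({c.upper() for c in autosomes})
    else:
        is_auto = chrom.str.fullmatch(r"\d+").fillna(False) & ~chrom.isin(_SEX_CHROMS)
    meta = pd.DataFrame(
        {
            "chromosome": bim["chromosome"],
            "position": pd.to_numeric(bim["position"], errors="coerce"),
            "is_autosomal": is_auto.to_numpy(dtype=bool),
        }
    )
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.animal_ids = list(fam["iid"])
    out.snp_ids = list(bim["snp_id"])
    out.dosages = dosages
    out.snp_meta = meta
    return out


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a bed/bim/fam triple (SNP-major); dosages count the A1 allele."""
    prefix = Path(prefix)
    n, m = g.n_animals, g.n_snps
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for a in g.animal_ids:
            fh.write(f"{a} {a} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, s in enumerate(g.snp_ids):
            if g.snp_meta is not None:
                chrom = g.snp_meta["chromosome"].iloc[j]
                pos = int(g.snp_meta["position"].iloc[j])
            else:
                chrom, pos = "1", j + 1
            fh.write(f"{chrom} {s} 0 {pos} A G\n")
    # encode: dosage 2 -> 00, 1 -> 10, 0 -> 11, missing -> 01
    codes = np.full((m, n), 3, dtype=np.uint8)
    d = g.dosages.T
    codes[np.isnan(d)] = 1
    codes[d == 1.0] = 2
    codes[d == 2.0] = 0
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(m, -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.tobytes())


def read_dosage_tsv(path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Plain-text fallback: TSV of animals x SNPs with NA for missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        animal_ids=list(map(str, df.index)),
        snp_ids=list(map(str, df.columns)),
        dosages=df.to_numpy(dtype=float),
        snp_meta=snp_meta,
    )


def write_grm_tsv(grm: GenomicRelationshipMatrix, path) -> None:
    pd.DataFrame(grm.values, index=grm.animal_ids, columns=grm.animal_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_grm_tsv(path, blend_weight: float = 0.0) -> GenomicRelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenomicRelationshipMatrix(list(map(str, df.index)), df.to_numpy(), blend_weight)
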