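"""Study orchestration and result aggregation.

Runs the per-OTU analysis loop (one recursive-model fit per OTU),
collects per-OTU result rows, and aggregates them into study-level
summaries: per-trait counts of significant OTUs with their overlap
(Venn counts), positive/negative splits, tables of "relevant" OTUs
(|standardized effect| >= 0.2 SD) sorted by effect magnitude,
family-level breakdowns extracted from taxonomy strings, and
heritability summaries.

The package ships the published tables of relevant OTUs and the
study-level counts as plain-text fixtures, so the aggregation logic can
be exercised against known numbers without refitting anything.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import re
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decomposition as dec
from .sem_core import ChainConfig, effective_sample_size, gibbs_sem

__all__ = [
    "StudySummary",
    "summarize",
    "run_study",
    "load_fixture_tables",
    "load_study_counts",
    "load_trait_descriptives",
    "extract_family",
]

logger = logging.getLogger(__name__)

_DATA = importlib.resources.files("gutsem") / "data"


def load_fixture_tables() -> pd.DataFrame:
    """The published tables of relevant OTUs, long format.

    One row per (OTU, trait): posterior mean/median of the structural
    coefficient, its HPD95% bounds, the SD-standardized effect and the
    lowest-rank taxonomy label. 15 rows for ADG_AL and 38 for ADG_R.
    """
    frames = []
    for trait, name in (("AL", "relevant_otu_adg_al.tsv"), ("R", "relevant_otu_adg_r.tsv")):
        with (_DATA / name).open() as fh:
            df = pd.read_csv(fh, sep="\t")
        df.insert(1, "trait", trait)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def load_study_counts() -> dict:
    """Published study-level counts of significant OTUs by trait and sign."""
    return json.loads((_DATA / "study_counts.json").read_text())


def load_trait_descriptives() -> dict:
    """Published descriptive statistics (n, mean, SD) of the ADG traits."""
    return json.loads((_DATA / "trait_descriptives.json").read_text())


_RANK_RE = re.compile(r"f__([^;]*)")


def extract_family(taxonomy: str | float) -> str:
    """Family-rank label from a taxonomy string.

    Understands rank-prefixed strings (``k__...;f__Lachnospiraceae;...``)
    and plain rank-labelled strings (``Family Lachnospiraceae``). Rows
    whose taxonomy stops above the family rank, or is malformed, fall in
    the "Unassigned" bucket.
    """
    if not isinstance(taxonomy, str) or not taxonomy.strip():
        return "Unassigned"
    tax = taxonomy.strip()
    m = _RANK_RE.search(tax)
    if m:
        return m.group(1).strip() or "Unassigned"
    m = re.match(r"Family\s+(.+)", tax)
    if m:
        return m.group(1).strip()
    if re.match(r"(Genus|Species|Order|Class|Phylum|Kingdom)\s+\S+", tax) or tax == "Unassigned":
        return "Unassigned"
    warnings.warn(f"malformed taxonomy string {tax!r}: assigning to 'Unassigned'", stacklevel=2)
    return "Unassigned"


@dataclass
class StudySummary:
    """Aggregated counts and tables over all analyzed OTUs."""

    n_significant: dict[str, int]
    n_positive: dict[str, int]
    n_negative: dict[str, int]
    n_relevant: dict[str, int]
    relevant_both_ids: list[str]
    pct_positive_relevant: dict[str, float]
    relevant_tables: dict[str, pd.DataFrame]
    family_breakdown: dict[str, dict[str, float]]
    heritability: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_al, n_r = self.n_significant["AL"], self.n_significant["R"]
        n_both = self.n_significant["both"]
        if n_both > min(n_al, n_r):
            raise ValueError("overlap cannot exceed either per-trait count")
        expected = n_al + n_r - n_both
        if self.n_significant.get("total", expected) != expected:
            raise ValueError("inclusion-exclusion identity violated")
        self.n_significant["total"] = expected

    def to_dict(self) -> dict:
        return {
            "n_significant": self.n_significant,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_relevant": self.n_relevant,
            "relevant_both_ids": self.relevant_both_ids,
            "pct_positive_relevant": self.pct_positive_relevant,
            "family_breakdown": self.family_breakdown,
            "heritability": self.heritability,
        }


def _as_long(results: pd.DataFrame) -> pd.DataFrame:
    """Accept either the long per-(OTU, trait) layout or the wide per-OTU
    layout produced by :func:`run_study` and return the long one."""
    if "trait" in results.columns:
        return results.copy()
    rows = []
    for _, row in results.iterrows():
        for trait in ("AL", "R"):
            rows.append(
                {
                    "otu_id": row["otu_id"],
                    "trait": trait,
                    "mean": row.get(f"lambda_{trait}_mean", np.nan),
                    "median": row.get(f"lambda_{trait}_median", np.nan),
                    "hpd_low": row.get(f"lambda_{trait}_hpd_low", np.nan),
                    "hpd_high": row.get(f"lambda_{trait}_hpd_high", np.nan),
                    "effect": row.get(f"std_effect_{trait}", np.nan),
                    "taxonomy": row.get("taxonomy", ""),
                    "h2_M_direct": row.get("h2_M_direct", np.nan),
                    "h2_AL_direct": row.get("h2_AL_direct", np.nan),
                    "h2_R_direct": row.get("h2_R_direct", np.nan),
                }
            )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame, relevance_threshold: float = 0.2) -> StudySummary:
    """Aggregate per-OTU results into a study summary.

    Significance is read from the HPD bounds (interval excluding zero),
    relevance from |standardized effect| >= threshold, and sign from the
    posterior mean. Percentages are computed from the stored counts.
    """
    empty = StudySummary(
        n_significant={"AL": 0, "R": 0, "both": 0},
        n_positive={"AL": 0, "R": 0, "both": 0},
        n_negative={"AL": 0, "R": 0, "both": 0},
        n_relevant={"AL": 0, "R": 0, "both": 0},
        relevant_both_ids=[],
        pct_positive_relevant={"AL": float("nan"), "R": float("nan")},
        relevant_tables={"AL": pd.DataFrame(), "R": pd.DataFrame()},
        family_breakdown={},
    )
    if len(results) == 0:
        return empty
    long = _as_long(results).dropna(subset=["mean", "hpd_low", "hpd_high"])
    if len(long) == 0:
        return empty
    long["significant"] = (long["hpd_low"] > 0) | (long["hpd_high"] < 0)
    long["relevant"] = long["significant"] & (long["effect"].abs() >= relevance_threshold)
    long["positive"] = long["mean"] > 0
    long["family"] = long["taxonomy"].map(extract_family)

    sig = {t: long[(long["trait"] == t) & long["significant"]] for t in ("AL", "R")}
    sig_ids = {t: set(sig[t]["otu_id"]) for t in ("AL", "R")}
    both_ids = sig_ids["AL"] & sig_ids["R"]
    pos_ids = {t: set(sig[t][sig[t]["positive"]]["otu_id"]) for t in ("AL", "R")}
    pos_both = {o for o in both_ids if o in pos_ids["AL"] and o in pos_ids["R"]}
    neg_ids = {t: sig_ids[t] - pos_ids[t] for t in ("AL", "R")}
    neg_both = {o for o in both_ids if o in neg_ids["AL"] and o in neg_ids["R"]}

    rel = {t: long[(long["trait"] == t) & long["relevant"]] for t in ("AL", "R")}
    rel_ids = {t: set(rel[t]["otu_id"]) for t in ("AL", "R")}
    rel_both = sorted(rel_ids["AL"] & rel_ids["R"])

    relevant_tables = {
        t: rel[t].assign(abs_effect=rel[t]["effect"].abs())
        .sort_values("abs_effect", ascending=False)
        .drop(columns="abs_effect")
        .reset_index(drop=True)
        for t in ("AL", "R")
    }
    pct_positive = {
        t: 100.0 * len(rel[t][rel[t]["positive"]]) / len(rel[t]) if len(rel[t]) else float("nan")
        for t in ("AL", "R")
    }

    family_breakdown: dict[str, dict[str, float]] = {}
    for t in ("AL", "R"):
        if len(sig[t]):
            counts = sig[t]["family"].value_counts()
            family_breakdown[t] = {
                fam: round(100.0 * k / len(sig[t]), 1) for fam, k in counts.items()
            }

    heritability: dict[str, dict[str, float]] = {}
    for col in ("h2_AL_direct", "h2_R_direct", "h2_M_direct"):
        if col in long.columns:
            per_otu = long.drop_duplicates("otu_id")[col].dropna()
            if len(per_otu):
                heritability[col] = {
                    "mean": float(per_otu.mean()),
                    "sd": float(per_otu.std(ddof=1)) if len(per_otu) > 1 else 0.0,
                }

    return StudySummary(
        n_significant={"AL": len(sig_ids["AL"]), "R": len(sig_ids["R"]), "both": len(both_ids)},
        n_positive={"AL": len(pos_ids["AL"]), "R": len(pos_ids["R"]), "both": len(pos_both)},
        n_negative={"AL": len(neg_ids["AL"]), "R": len(neg_ids["R"]), "both": len(neg_both)},
        n_relevant={"AL": len(rel_ids["AL"]), "R": len(rel_ids["R"]), "both": len(rel_both)},
        relevant_both_ids=rel_both,
        pct_positive_relevant=pct_positive,
        relevant_tables=relevant_tables,
        family_breakdown=family_breakdown,
        heritability=heritability,
    )


def _otu_seed(base_seed: int, otu_index: int) -> int:
    return int(np.random.SeedSequence((base_seed, otu_index)).generate_state(1)[0] % (2**31))


def run_study(
    phenotypes,
    norm_table,
    grm,
    out_path,
    chain_config: ChainConfig | None = None,
    otu_ids: list[str] | None = None,
    trait_sd: dict[str, float] | None = None,
    base_seed: int = 0,
    hpd_prob: float = 0.95,
    relevance_threshold: float = 0.2,
    resume: bool = True,
) -> tuple[pd.DataFrame, StudySummary]:
    """Fit the recursive model once per OTU and aggregate the results.

    Writes one result row per OTU to ``out_path`` (TSV) in deterministic
    OTU order; with ``resume=True`` OTUs already present in an existing
    output file are skipped and their rows reused, so an interrupted run
    finishes to the identical file. A sampler failure for one OTU is
    logged and recorded as an NA row; the loop continues. Each OTU gets
    a seed derived deterministically from ``base_seed`` and its position
    in the full OTU list.
    """
    from .preprocess import assemble_sem_dataset

    out_path = Path(out_path)
    chain_config = chain_config or ChainConfig()
    all_ids = list(norm_table.otu_ids)
    wanted = all_ids if otu_ids is None else [o for o in all_ids if o in set(otu_ids)]
    if trait_sd is None:
        trait_sd = {
            "AL": float(np.nanstd(phenotypes.frame.loc[phenotypes.frame.regime == "AL", "adg"], ddof=1)),
            "R": float(np.nanstd(phenotypes.frame.loc[phenotypes.frame.regime == "R", "adg"], ddof=1)),
        }

    done: dict[str, dict] = {}
    if resume and out_path.exists():
        prev = pd.read_csv(out_path, sep="\t")
        done = {str(r["otu_id"]): r.to_dict() for _, r in prev.iterrows()}

    rows = []
    for otu in wanted:
        if otu in done:
            rows.append(done[otu])
            continue
        seed = _otu_seed(base_seed, all_ids.index(otu))
        cfg = ChainConfig(**{**vars(chain_config), "seed": seed})
        t0 = time.perf_counter()
        try:
            data = assemble_sem_dataset(phenotypes, norm_table, otu, grm)
            samples = gibbs_sem(data, cfg)
            result = dec.decompose_samples(
                samples, trait_sd, hpd_prob=hpd_prob, relevance_threshold=relevance_threshold
            )
            row = result.to_row(taxonomy=norm_table.taxonomy.get(otu, ""))
            ess = effective_sample_size(samples.lambda_r)
            logger.info(
                "otu=%s seed=%d ess_lambda_R=%.0f runtime=%.2fs",
                otu, seed, ess, time.perf_counter() - t0,
            )
        except Exception as exc:  # noqa: BLE001 — one bad OTU must not kill the study
            logger.warning("otu=%s failed: %s", otu, exc)
            row = {"otu_id": otu, "taxonomy": norm_table.taxonomy.get(otu, "")}
        rows.append(row)
        pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)

    results = pd.DataFrame(rows)
    results.to_csv(out_path, sep="\t", index=False)
    return results, summarize(results, relevance_threshold)
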