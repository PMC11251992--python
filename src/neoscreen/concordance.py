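"""Predictor-rank integration: concordance statistics and targeted-panel selection.

External pMHC predictors report percentile ranks per (peptide, allele): a
binding-affinity (BA) rank and an eluted-ligand (EL) rank, where lower means
stronger; rank <= 2 is the conventional "predicted presented" call. This
module joins those calls with TR-FRET stable-binder calls, quantifies
agreement, and applies the union rule that forms the targeted-MS panel:
every peptide that is a TR-FRET stable binder (RZ >= 5), plus peptides that
miss that bar but are predicted binders (rank <= 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANK_COLUMNS = ["peptide", "allele", "ba_rank", "el_rank"]

ARM_TRFRET = "trfret"
ARM_PREDICTION_ONLY = "prediction_only"


def classify_predicted(rank: float, threshold: float = 2.0) -> bool:
    """Predicted binder iff percentile rank <= threshold (inclusive).

    A missing rank classifies as non-binder, with a warning.
    """
    if rank is None or (isinstance(rank, float) and np.isnan(rank)):
        logger.warning("missing predictor rank classified as non-binder")
        return False
    if rank < 0:
        raise ValueError(f"percentile rank must be nonnegative, got {rank}")
    return rank <= threshold


def _rank_column(which_rank: str) -> str:
    if which_rank not in ("ba", "el"):
        raise ValueError("which_rank must be 'ba' or 'el'")
    return f"{which_rank}_rank"


def _join(screen: pd.DataFrame, ranks: pd.DataFrame, rank_col: str) -> pd.DataFrame:
    missing = [c for c in RANK_COLUMNS if c not in ranks.columns]
    if missing:
        raise ValueError(f"rank table is missing columns: {missing}")
    if ranks.duplicated(["peptide", "allele"]).any():
        raise ValueError("rank table has duplicate (peptide, allele) rows")
    merged = screen.merge(
        ranks[["peptide", "allele", rank_col]], on=["peptide", "allele"], how="left"
    )
    n_unmatched = int(merged[rank_col].isna().sum())
    if n_unmatched:
        logger.warning(
            "%d screened pairs have no predictor rank; classified non-binders",
            n_unmatched,
        )
    return merged


def _summary_row(allele: str, sub: pd.DataFrame) -> dict:
    trfret = sub["stable_binder"].to_numpy(dtype=bool)
    pred = sub["predicted_binder"].to_numpy(dtype=bool)
    n = len(sub)
    n_both = int((trfret & pred).sum())
    n_union = int((trfret | pred).sum())
    n_neither = n - n_union
    return {
        "allele": allele,
        "n_pairs": n,
        "n_trfret_binders": int(trfret.sum()),
        "n_pred_binders": int(pred.sum()),
        "n_both": n_both,
        "n_neither": n_neither,
        "pct_agreement_binders": 100.0 * n_both / n_union if n_union else None,
        "pct_both_of_all": 100.0 * n_both / n if n else None,
        "pct_agreement_nonbinders": (
            100.0 * n_neither / (n - n_both) if n - n_both else None
        ),
    }


def concordance(
    screen: pd.DataFrame,
    ranks: pd.DataFrame,
    which_rank: str = "ba",
    rank_threshold: float = 2.0,
) -> pd.DataFrame:
    """Agreement between TR-FRET and predictor binder calls, per allele and overall.

    ``screen`` needs columns ``peptide, allele, stable_binder``. Agreement
    among binders is Jaccard-style: |both| / |either-binder union|, reported
    as a percentage (null when no pair is called by either method). Also
    reports |both| / |all pairs| and the analogous agreement among
    non-binders.
    """
    rank_col = _rank_column(which_rank)
    merged = _join(screen, ranks, rank_col)
    merged["predicted_binder"] = merged[rank_col].le(rank_threshold).fillna(False)
    rows = [
        _summary_row(allele, sub) for allele, sub in merged.groupby("allele", sort=True)
    ]
    rows.append(_summary_row("overall", merged))
    return pd.DataFrame(rows)


@dataclass
class PanelSelection:
    """The targeted-MS peptide panel and its allele-specific pools.

    ``table`` has one row per selected peptide with its arm:
    ``trfret`` (best RZ over alleles >= rz_threshold) or ``prediction_only``
    (best RZ below threshold but best rank <= rank_threshold). The arms are
    exclusive by construction. ``allele_pools`` maps each allele to the
    peptides selected for it by either criterion; a peptide may sit in
    several pools.
    """

    table: pd.DataFrame
    allele_pools: dict[str, list[str]] = field(default_factory=dict)

    @property
    def peptides(self) -> set[str]:
        return set(self.table["peptide"])

    def arm_counts(self) -> dict[str, int]:
        return self.table["arm"].value_counts().to_dict()


def select_targeted_panel(
    screen: pd.DataFrame,
    ranks: pd.DataFrame,
    rz_threshold: float = 5.0,
    rank_threshold: float = 2.0,
    which_rank: str = "el",
) -> PanelSelection:
    """Apply the union rule selecting peptides for targeted-MS follow-up.

    Per peptide, aggregate over alleles by best score (max RZ, min rank).
    Selected iff max RZ >= ``rz_threshold`` (arm ``trfret``) or, failing
    that, min rank <= ``rank_threshold`` (arm ``prediction_only``). Pools
    assign each selected peptide to every allele for which either criterion
    holds at the (peptide, allele) level. ``screen`` is expected QC-filtered
    (see :func:`neoscreen.trfret.call_stable_binders`).
    """
    rank_col = _rank_column(which_rank)
    merged = _join(screen, ranks, rank_col)
    merged["rz_score"] = merged["rz_score"].astype(float)

    per_peptide = merged.groupby("peptide").agg(
        max_rz=("rz_score", "max"), min_rank=(rank_col, "min")
    )
    no_score = per_peptide["max_rz"].isna() & per_peptide["min_rank"].isna()
    if no_score.any():
        logger.warning(
            "%d peptides have neither an RZ-score nor a rank; skipped",
            int(no_score.sum()),
        )
        per_peptide = per_peptide[~no_score]

    trfret_arm = per_peptide["max_rz"] >= rz_threshold
    pred_arm = ~trfret_arm & (per_peptide["min_rank"] <= rank_threshold)
    table = per_peptide[trfret_arm | pred_arm].copy()
    table["arm"] = np.where(
        table["max_rz"] >= rz_threshold, ARM_TRFRET, ARM_PREDICTION_ONLY
    )
    table = table.reset_index()[["peptide", "arm", "max_rz", "min_rank"]]

    selected = set(table["peptide"])
    pair_hit = merged[
        merged["peptide"].isin(selected)
        & (
            (merged["rz_score"] >= rz_threshold)
            | (merged[rank_col] <= rank_threshold)
        )
    ]
    allele_pools = {
        allele: sorted(sub["peptide"].unique())
        for allele, sub in pair_hit.groupby("allele", sort=True)
    }
    return PanelSelection(table=table, allele_pools=allele_pools)


def read_ranks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RANK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rank table is missing columns: {missing}")
    return df
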