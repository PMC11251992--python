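"""Recomputation of study-level summary counts from screen and MS tables.

Given a full screen table (one row per screened neoepitope-HLA pair with
its TR-FRET RZ-score and predictor ranks) and detection tables from
targeted and untargeted MS, these helpers recompute the headline counts of
a discovery campaign: pairs screened, candidate pairs by either method,
targeted-panel arm sizes, and the both-method concordance among detected
pairs. They operate on user-supplied TSV extracts of such tables; column
names follow the package's screen/rank conventions.
"""

from __future__ import annotations

import pandas as pd

from .concordance import select_targeted_panel


def summarize_screen_table(
    screen: pd.DataFrame,
    rz_threshold: float = 5.0,
    rank_threshold: float = 2.0,
    which_rank: str = "el",
) -> dict:
    """Headline counts from a screened-pair table.

    ``screen`` needs one row per (peptide, allele) with columns
    ``peptide, allele, rz_score`` and the rank column(s) ``ba_rank`` /
    ``el_rank``. Returns pairs screened, stable-binder pairs, predicted
    pairs, candidate pairs (either method), both-method pairs and the
    both-method percentage of all pairs, plus peptide-level panel arm sizes
    under the union rule.
    """
    rank_col = f"{which_rank}_rank"
    if rank_col not in screen.columns:
        raise ValueError(f"screen table is missing column {rank_col}")
    trfret = screen["rz_score"] >= rz_threshold
    pred = screen[rank_col] <= rank_threshold
    n_pairs = len(screen)
    n_both = int((trfret & pred).sum())

    records = screen[["peptide", "allele", "rz_score"]].copy()
    records["stable_binder"] = trfret
    ranks = screen[["peptide", "allele"]].copy()
    ranks["ba_rank"] = screen.get("ba_rank")
    ranks["el_rank"] = screen.get("el_rank")
    panel = select_targeted_panel(
        records, ranks,
        rz_threshold=rz_threshold,
        rank_threshold=rank_threshold,
        which_rank=which_rank,
    )
    arms = panel.arm_counts()
    return {
        "n_pairs_screened": n_pairs,
        "n_trfret_binder_pairs": int(trfret.sum()),
        "n_predicted_pairs": int(pred.sum()),
        "n_candidate_pairs": int((trfret | pred).sum()),
        "n_both_method_pairs": n_both,
        "pct_both_of_all": 100.0 * n_both / n_pairs if n_pairs else None,
        "n_panel_trfret_peptides": arms.get("trfret", 0),
        "n_panel_prediction_only_peptides": arms.get("prediction_only", 0),
        "n_panel_peptides": len(panel.table),
    }


def summarize_detections(
    detections: pd.DataFrame,
    screen: pd.DataFrame,
    rz_threshold: float = 5.0,
    rank_threshold: float = 2.0,
    which_rank: str = "el",
) -> dict:
    """Both-method concordance among MS-detected neoepitope-HLA pairs.

    ``detections`` has one row per detected (peptide, allele) pair;
    ``screen`` as in :func:`summarize_screen_table`. Returns the number of
    detected pairs and how many of them were binders by both, one, or
    neither upstream method.
    """
    rank_col = f"{which_rank}_rank"
    merged = detections[["peptide", "allele"]].drop_duplicates().merge(
        screen[["peptide", "allele", "rz_score", rank_col]],
        on=["peptide", "allele"],
        how="left",
    )
    trfret = merged["rz_score"] >= rz_threshold
    pred = merged[rank_col] <= rank_threshold
    return {
        "n_detected_pairs": len(merged),
        "n_both_methods": int((trfret & pred).sum()),
        "n_trfret_only": int((trfret & ~pred).sum()),
        "n_predicted_only": int((~trfret & pred).sum()),
        "n_neither": int((~trfret & ~pred).sum()),
    }
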