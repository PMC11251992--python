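"""Selection of shared cancer mutations and prevalent HLA class I alleles.

Shared neoantigens arise from recurrent somatic point mutations (KRAS G12D,
BRAF V600E, ...). A neoepitope-HLA discovery campaign starts by picking the
mutations that recur in a meaningful fraction of cases of at least one
indication, and the HLA alleles common enough in the target population to
matter clinically. Both selections are simple threshold filters over
pre-extracted frequency tables; this module implements them with inclusive
("at least") thresholds.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ["gene", "protein_change", "indication", "case_prevalence"]
FREQ_COLUMNS = ["allele", "population", "allele_frequency"]
TYPING_COLUMNS = ["subject", "allele"]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {missing}")


def select_mutations(
    prevalence: pd.DataFrame, threshold: float = 0.02
) -> pd.DataFrame:
    """Select mutations whose maximum per-indication case prevalence meets a threshold.

    Parameters
    ----------
    prevalence
        Long table with columns ``gene``, ``protein_change``, ``indication``,
        ``case_prevalence`` (fraction of cases of that indication carrying the
        mutation). A mutation may appear under several indications.
    threshold
        Minimum per-indication case prevalence, inclusive. Default 0.02 (2%).

    Returns
    -------
    One row per selected (gene, protein_change), deduplicated across
    indications, with the maximum prevalence and the indication attaining it,
    sorted by decreasing prevalence.
    """
    _require_columns(prevalence, MUTATION_COLUMNS, "mutation prevalence")
    if prevalence.empty:
        return pd.DataFrame(
            columns=["gene", "protein_change", "max_prevalence", "top_indication"]
        )
    bad = prevalence[
        (prevalence["case_prevalence"] < 0) | (prevalence["case_prevalence"] > 1)
    ]
    if not bad.empty:
        raise ValueError("case_prevalence values must lie in [0, 1]")

    idx = prevalence.groupby(["gene", "protein_change"], sort=False)[
        "case_prevalence"
    ].idxmax()
    best = prevalence.loc[idx, MUTATION_COLUMNS].rename(
        columns={"case_prevalence": "max_prevalence", "indication": "top_indication"}
    )
    selected = best[best["max_prevalence"] >= threshold]
    return (
        selected.sort_values(
            ["max_prevalence", "gene", "protein_change"],
            ascending=[False, True, True],
        )
        .reset_index(drop=True)[
            ["gene", "protein_change", "max_prevalence", "top_indication"]
        ]
    )


def carrier_frequencies(typing: pd.DataFrame) -> pd.Series:
    """Fraction of typed subjects carrying >= 1 copy of each allele.

    ``typing`` is a long table (``subject``, ``allele``) with one row per
    allele call; a homozygous subject contributes two identical rows but is
    counted once.
    """
    _require_columns(typing, TYPING_COLUMNS, "typing")
    n_subjects = typing["subject"].nunique()
    if n_subjects == 0:
        return pd.Series(dtype=float, name="carrier_frequency")
    carriers = typing.drop_duplicates(["subject", "allele"]).groupby("allele").size()
    out = (carriers / n_subjects).rename("carrier_frequency")
    return out


def select_alleles(
    freq: pd.DataFrame,
    typing: pd.DataFrame,
    min_overall_af: float = 0.05,
    min_carrier: float = 0.10,
    floor_af: float = 0.01,
) -> pd.DataFrame:
    """Select prevalent HLA alleles from population frequencies plus cohort typings.

    The filter chain:

    1. drop alleles whose allele frequency is below ``floor_af`` in *every*
       population (rare everywhere);
    2. overall allele frequency = unweighted mean across populations with a
       reported value (missing populations are skipped and logged);
    3. carrier frequency = fraction of typed subjects carrying >= 1 copy
       (a homozygote counts once);
    4. keep alleles with overall AF >= ``min_overall_af`` AND carrier
       frequency >= ``min_carrier``; thresholds are inclusive.

    Returns a table ranked by overall allele frequency, descending. Alleles
    seen in the typing cohort but absent from the frequency table cannot pass
    the frequency filter and are excluded (logged).
    """
    _require_columns(freq, FREQ_COLUMNS, "allele frequency")
    for thr in (min_overall_af, min_carrier, floor_af):
        if not 0 < thr < 1:
            raise ValueError("thresholds must lie in (0, 1)")

    n_before = len(freq)
    freq = freq.dropna(subset=["allele_frequency"])
    if len(freq) < n_before:
        logger.info(
            "skipped %d allele-frequency rows with missing values",
            n_before - len(freq),
        )
    if ((freq["allele_frequency"] < 0) | (freq["allele_frequency"] > 1)).any():
        raise ValueError("allele_frequency values must lie in [0, 1]")

    by_allele = freq.groupby("allele")["allele_frequency"]
    passes_floor = by_allele.max() >= floor_af
    dropped = passes_floor[~passes_floor].index.tolist()
    if dropped:
        logger.info(
            "removed %d alleles below floor AF %.3f in all populations: %s",
            len(dropped), floor_af, dropped,
        )
    overall = by_allele.mean()[passes_floor].rename("overall_af")

    carrier = carrier_frequencies(typing)
    typed_only = sorted(set(carrier.index) - set(freq["allele"]))
    if typed_only:
        logger.warning(
            "%d alleles present in typing but absent from the frequency table "
            "were excluded: %s", len(typed_only), typed_only,
        )

    table = pd.concat([overall, carrier], axis=1, join="inner")
    table = table[
        (table["overall_af"] >= min_overall_af)
        & (table["carrier_frequency"] >= min_carrier)
    ]
    return (
        table.sort_index()
        .sort_values("overall_af", ascending=False, kind="stable")
        .rename_axis("allele")
        .reset_index()
    )


def read_mutation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, MUTATION_COLUMNS, "mutation prevalence")
    return df


def read_allele_frequencies(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, FREQ_COLUMNS, "allele frequency")
    return df


def read_typing(path) -> pd.DataFrame:
    """Read a typing TSV: one row per (subject, allele) call."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TYPING_COLUMNS, "typing")
    return df
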