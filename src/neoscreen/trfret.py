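"""TR-FRET peptide-exchange plate statistics and stable-binder calling.

The screen measures stability of peptide-HLA complexes after UV-triggered
peptide exchange in 384-well plates. Each well reports donor (615 nm) and
acceptor (665 nm) fluorescence; the working signal is the ratiometric

    RFU ratio = (RFU_665 / RFU_615) * 1e4.

Normalization is per plate, against the no-peptide (+HLA) negative controls:

    %DeltaF = 100 * (ratio_sample - mean(ratio_neg)) / mean(ratio_neg)
    RZ      = (%DeltaF_sample - median(%DeltaF_neg)) / (1.4826 * MAD)

RZ >= 5 on a plate passing Z-factor QC (Z' > 0.4, computed from the
positive/negative exchange controls) calls a stable binder.

The robust scale (MAD) in the plate-level pipeline is taken from the
plate's sample-well %DeltaF distribution by default rather than from the
handful of negative wells: a MAD estimated from ~8 negatives is so noisy
that its sampling error, not the assay, dominates the RZ tail and
manufactures false positives; the ~350 sample wells give a stable scale
and are themselves overwhelmingly null at realistic hit rates. The
negatives-only scale remains available (``rz_scale="negatives"``), and the
standalone :func:`robust_zscore` uses negatives as its reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePlateError,
    InvalidWellError,
    PlateInvalidError,
    UndefinedZFactorError,
)

logger = logging.getLogger(__name__)

ROLE_SAMPLE = "sample"
ROLE_POS = "pos_ctrl"
ROLE_NEG_NO_PEPTIDE = "neg_ctrl_no_peptide"
ROLE_NEG_NO_HLA = "neg_ctrl_no_hla"
ROLES = (ROLE_SAMPLE, ROLE_POS, ROLE_NEG_NO_PEPTIDE, ROLE_NEG_NO_HLA)

#: consistency constant making 1.4826 * MAD estimate sigma for normal data
MAD_SCALE = 1.4826

DEFAULT_BINDER_THRESHOLD = 5.0
DEFAULT_QC_THRESHOLD = 0.4

PLATE_COLUMNS = ["plate_id", "well", "role", "peptide", "allele", "rfu_665", "rfu_615"]


def rfu_ratio(rfu_665: float, rfu_615: float) -> float:
    """Acceptor/donor ratio scaled by 1e4. Donor channel must be positive."""
    if rfu_615 <= 0:
        raise InvalidWellError(f"donor channel must be positive, got {rfu_615}")
    if rfu_665 < 0:
        raise InvalidWellError(f"acceptor channel must be nonnegative, got {rfu_665}")
    return (rfu_665 / rfu_615) * 1e4


def percent_deltaf(sample_ratio: float, neg_ratios: Sequence[float]) -> float:
    """Percent signal change of a well over the plate's negative-control mean."""
    neg = np.asarray(neg_ratios, dtype=float)
    if neg.size < 2:
        raise PlateInvalidError(
            f"need >= 2 negative-control wells, got {neg.size}"
        )
    mean_neg = float(neg.mean())
    if mean_neg <= 0:
        raise PlateInvalidError(f"negative-control mean must be positive, got {mean_neg}")
    return (sample_ratio - mean_neg) / mean_neg * 100.0


def robust_zscore(sample_deltaf: float, neg_deltafs: Sequence[float]) -> float:
    """Robust Z of a sample %DeltaF against the plate's negative controls.

    Uses median/MAD with the 1.4826 consistency constant. A zero MAD falls
    back to the sample standard deviation of the negatives (logged); if that
    is also zero the plate is degenerate.
    """
    neg = np.asarray(neg_deltafs, dtype=float)
    if neg.size < 2:
        raise PlateInvalidError(
            f"need >= 2 negative-control wells, got {neg.size}"
        )
    med = float(np.median(neg))
    mad = float(np.median(np.abs(neg - med)))
    if mad > 0:
        return (sample_deltaf - med) / (MAD_SCALE * mad)
    sd = float(np.std(neg, ddof=1))
    if sd > 0:
        logger.warning("negative-control MAD is 0; falling back to standard deviation")
        return (sample_deltaf - med) / sd
    raise DegeneratePlateError("negative controls have zero dispersion")


def z_factor(
    pos_values: Sequence[float],
    neg_values: Sequence[float],
    as_printed: bool = False,
) -> float:
    """Plate-quality Z' statistic from positive and negative control wells.

    Default is the standard screening-window coefficient
    ``1 - 3*(sd_pos + sd_neg) / |mean_pos - mean_neg|``. With
    ``as_printed=True`` the variant with a *difference* of the 3-s.d. terms is
    computed instead, for auditing pipelines that used that form.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise PlateInvalidError("need >= 2 wells in each control group")
    delta = float(pos.mean() - neg.mean())
    if delta == 0:
        raise UndefinedZFactorError("control group means coincide")
    sd_pos = float(np.std(pos, ddof=1))
    sd_neg = float(np.std(neg, ddof=1))
    if as_printed:
        return 1.0 - (3.0 * sd_pos - 3.0 * sd_neg) / delta
    return 1.0 - 3.0 * (sd_pos + sd_neg) / abs(delta)


@dataclass
class PlateStats:
    plate_id: str
    z_factor: float
    qc_pass: bool
    neg_mean_ratio: float
    neg_median_deltaf: float
    neg_mad_deltaf: float
    n_pos: int
    n_neg: int


def _validate_plate_table(plates: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plates.columns]
    if missing:
        raise ValueError(f"plate table is missing columns: {missing}")
    bad_roles = set(plates["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown well roles: {sorted(bad_roles)}")
    samples = plates[plates["role"] == ROLE_SAMPLE]
    if samples["peptide"].isna().any():
        raise ValueError("sample wells must carry a peptide")


def process_plates(
    plates: pd.DataFrame,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
    rz_scale: str = "samples",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-plate QC statistics and per-sample-well screen records.

    Parameters
    ----------
    plates
        One row per well with columns ``plate_id, well, role, peptide,
        allele, rfu_665, rfu_615``.
    qc_threshold
        Plates qualify when Z-factor strictly exceeds this value.
    rz_scale
        Where the robust scale of the RZ denominator comes from:
        ``"samples"`` (default) uses the MAD of the plate's sample-well
        %DeltaF values (stable, ~350 wells); ``"negatives"`` uses the MAD
        of the negative controls only. The RZ center is the negative-control
        median either way, so the negative median always scores exactly 0.
        Plates with too few sample wells (< 8) fall back to the negatives.

    Returns
    -------
    (plate_stats, records)
        ``plate_stats`` has one row per plate (z_factor, qc_pass, negative
        control summaries); ``records`` one row per sample well (rfu_ratio,
        percent_deltaf, rz_score), QC-passing and failing plates alike --
        binder calling downstream drops failing plates.
    """
    if rz_scale not in ("samples", "negatives"):
        raise ValueError("rz_scale must be 'samples' or 'negatives'")
    _validate_plate_table(plates)
    stats_rows: list[dict] = []
    record_frames: list[pd.DataFrame] = []
    for plate_id, plate in plates.groupby("plate_id", sort=True):
        if (plate["rfu_615"] <= 0).any():
            raise InvalidWellError(
                f"plate {plate_id}: donor channel must be positive in every well"
            )
        ratio = (plate["rfu_665"] / plate["rfu_615"]) * 1e4
        neg_mask = plate["role"] == ROLE_NEG_NO_PEPTIDE
        pos_mask = plate["role"] == ROLE_POS
        n_neg = int(neg_mask.sum())
        n_pos = int(pos_mask.sum())
        if n_pos < 4:
            logger.warning("plate %s: only %d positive-control wells (<4)", plate_id, n_pos)
        if n_neg < 8:
            logger.warning("plate %s: only %d negative-control wells (<8)", plate_id, n_neg)
        if n_neg < 2:
            raise PlateInvalidError(
                f"plate {plate_id}: need >= 2 no-peptide negative controls"
            )
        neg_ratio = ratio[neg_mask].to_numpy(dtype=float)
        neg_mean = float(neg_ratio.mean())
        if neg_mean <= 0:
            raise PlateInvalidError(
                f"plate {plate_id}: negative-control mean ratio must be positive"
            )
        deltaf = (ratio - neg_mean) / neg_mean * 100.0
        neg_deltaf = deltaf[neg_mask].to_numpy(dtype=float)
        sample_mask = plate["role"] == ROLE_SAMPLE
        med = float(np.median(neg_deltaf))
        mad = float(np.median(np.abs(neg_deltaf - med)))

        scale_values = neg_deltaf
        if rz_scale == "samples":
            sample_deltaf = deltaf[sample_mask].to_numpy(dtype=float)
            if sample_deltaf.size >= 8:
                scale_values = sample_deltaf
            else:
                logger.warning(
                    "plate %s: only %d sample wells; RZ scale falls back to "
                    "negative controls", plate_id, sample_deltaf.size,
                )
        scale_med = float(np.median(scale_values))
        scale_mad = float(np.median(np.abs(scale_values - scale_med)))
        if scale_mad > 0:
            scale = MAD_SCALE * scale_mad
        else:
            sd = float(np.std(scale_values, ddof=1))
            if sd == 0:
                raise DegeneratePlateError(
                    f"plate {plate_id}: reference wells have zero dispersion"
                )
            logger.warning(
                "plate %s: reference MAD is 0; using standard deviation", plate_id
            )
            scale = sd
        rz = (deltaf - med) / scale

        if n_pos >= 2:
            zf = z_factor(ratio[pos_mask], neg_ratio)
        else:
            zf = math.nan
        qc = bool(zf > qc_threshold) if not math.isnan(zf) else False
        stats_rows.append(
            {
                "plate_id": plate_id,
                "z_factor": zf,
                "qc_pass": qc,
                "neg_mean_ratio": neg_mean,
                "neg_median_deltaf": med,
                "neg_mad_deltaf": mad,
                "n_pos": n_pos,
                "n_neg": n_neg,
            }
        )
        rec = plate.loc[sample_mask, ["peptide", "allele", "well"]].copy()
        rec["plate_id"] = plate_id
        rec["rfu_ratio"] = ratio[sample_mask]
        rec["percent_deltaf"] = deltaf[sample_mask]
        rec["rz_score"] = rz[sample_mask]
        record_frames.append(rec)

    plate_stats = pd.DataFrame(stats_rows)
    records = (
        pd.concat(record_frames, ignore_index=True)
        if record_frames
        else pd.DataFrame(
            columns=["peptide", "allele", "well", "plate_id", "rfu_ratio",
                     "percent_deltaf", "rz_score"]
        )
    )
    return plate_stats, records


def call_stable_binders(
    records: pd.DataFrame,
    plate_stats: pd.DataFrame,
    threshold: float = DEFAULT_BINDER_THRESHOLD,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> pd.DataFrame:
    """Call stable binders (RZ >= threshold, inclusive) on QC-passing plates.

    Records from plates with Z-factor <= ``qc_threshold`` are excluded with a
    warning, never silently called. Returns the retained records with a
    boolean ``stable_binder`` column.
    """
    qc = plate_stats.set_index("plate_id")["z_factor"] > qc_threshold
    known = records["plate_id"].isin(qc.index)
    if not known.all():
        raise ValueError("records reference plates absent from plate_stats")
    keep = records["plate_id"].map(qc)
    n_dropped = int((~keep).sum())
    if n_dropped:
        failed = sorted(records.loc[~keep, "plate_id"].unique())
        logger.warning(
            "excluded %d records from %d QC-failing plates (Z-factor <= %.2f): %s",
            n_dropped, len(failed), qc_threshold, failed,
        )
    out = records[keep].copy()
    out["stable_binder"] = out["rz_score"] >= threshold
    return out.reset_index(drop=True)


def read_plates(path) -> pd.DataFrame:
    """Read a plate CSV (one row per well)."""
    df = pd.read_csv(path)
    _validate_plate_table(df)
    return df
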