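"""Readthrough quantification for dual-reporter assays.

Dual-luciferase reporters: firefly luciferase (FLuc) is produced only on
readthrough, Renilla luciferase (RLuc) reports transfection/expression.
After background correction, relative luminescence is FLuc/RLuc;
readthrough efficiency is that ratio as a percentage of the sense-codon
control (stop mutated to a sense codon, defining 100% readthrough); and
relative readthrough levels rescale efficiencies to a chosen reference
construct (set to 1).

Dual-fluorescence in vivo reporters: mCD8 marks expressing cells, GFP is
the readthrough product; the GFP/mCD8 ratio of background-subtracted,
area-normalized intensities quantifies readthrough, optionally adjusted
to a reference mCD8 mean to correct for construct-dependent expression.

Statistical testing is out of scope; the table helpers emit tidy frames
for external stats tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Literal, Mapping, Optional

import pandas as pd

__all__ = [
    "LuminescenceRecord",
    "ImagingRecord",
    "relative_luminescence",
    "readthrough_efficiency",
    "relative_readthrough_level",
    "invivo_readthrough_ratio",
    "efficiency_table",
    "PLATE_COLUMNS",
]

PLATE_COLUMNS = ["construct_id", "fluc", "rluc", "fluc_bg", "rluc_bg"]


@dataclass(frozen=True)
class LuminescenceRecord:
    """One well: raw FLuc/RLuc counts plus their backgrounds."""

    construct_id: str
    fluc_raw: float
    rluc_raw: float
    fluc_background: float = 0.0
    rluc_background: float = 0.0

    def __post_init__(self) -> None:
        if self.fluc_raw < 0 or self.rluc_raw < 0:
            raise ValueError("raw luminescence must be >= 0")


@dataclass(frozen=True)
class ImagingRecord:
    """One organ/animal: area-normalized GFP and mCD8 intensities."""

    genotype_id: str
    gfp_signal_per_area: float
    gfp_background_per_area: float
    mcd8_signal_per_area: float
    mcd8_background_per_area: float
    reference_mcd8_mean: Optional[float] = None


def relative_luminescence(r: LuminescenceRecord) -> float:
    """Background-corrected FLuc/RLuc ratio.

    Raises when the corrected RLuc is not positive (failed transfection
    control); warns when the corrected FLuc is negative.
    """
    rluc = r.rluc_raw - r.rluc_background
    if rluc <= 0:
        raise ValueError(
            f"{r.construct_id}: invalid transfection control "
            f"(corrected RLuc = {rluc:g})"
        )
    fluc = r.fluc_raw - r.fluc_background
    if fluc < 0:
        warnings.warn(
            f"{r.construct_id}: corrected FLuc negative ({fluc:g}); "
            f"background exceeds signal"
        )
    return fluc / rluc


def readthrough_efficiency(test_mean: float, sense_control_mean: float) -> float:
    """Readthrough efficiency in percent: 100 x test / sense control.

    The sense-codon control (stop codon mutated to a sense codon) defines
    100% readthrough.
    """
    if sense_control_mean <= 0:
        raise ValueError(
            f"sense control mean must be positive, got {sense_control_mean:g}"
        )
    return 100.0 * test_mean / sense_control_mean


def relative_readthrough_level(
    efficiencies: Mapping[str, float], reference: str
) -> Dict[str, float]:
    """Efficiencies rescaled so the reference construct is exactly 1."""
    if reference not in efficiencies:
        raise ValueError(f"reference construct {reference!r} missing")
    ref = efficiencies[reference]
    if ref <= 0:
        raise ValueError(f"reference efficiency must be positive, got {ref:g}")
    out = {k: v / ref for k, v in efficiencies.items()}
    out[reference] = 1.0
    return out


def invivo_readthrough_ratio(
    r: ImagingRecord,
    mode: Literal["raw", "adjusted"] = "adjusted",
    direction: Literal["multiply", "divide"] = "multiply",
) -> float:
    """GFP/mCD8 readthrough ratio from area-normalized intensities.

    ``raw``: (GFP_signal - GFP_background) / (mCD8_signal -
    mCD8_background).  ``adjusted`` additionally rescales by the
    sample's corrected mCD8 over ``reference_mcd8_mean`` (or its
    inverse with ``direction='divide'``), correcting for
    construct-dependent expression differences against a reference
    genotype.
    """
    mcd8 = r.mcd8_signal_per_area - r.mcd8_background_per_area
    if mcd8 <= 0:
        raise ValueError(
            f"{r.genotype_id}: non-positive corrected mCD8 ({mcd8:g})"
        )
    gfp = r.gfp_signal_per_area - r.gfp_background_per_area
    ratio = gfp / mcd8
    if mode == "raw":
        return ratio
    if r.reference_mcd8_mean is None or r.reference_mcd8_mean <= 0:
        raise ValueError("adjusted mode requires a positive reference_mcd8_mean")
    scale = mcd8 / r.reference_mcd8_mean
    return ratio * scale if direction == "multiply" else ratio / scale


def efficiency_table(
    plate: pd.DataFrame,
    sense_control: str,
    reference: Optional[str] = None,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Readthrough efficiencies from a plate-reader table.

    *plate* needs columns ``construct_id, fluc, rluc, fluc_bg, rluc_bg``
    (one row per well).  By default per-construct means of the FLuc/RLuc
    ratios are taken before the efficiency ratio; ``per_replicate=True``
    instead computes an efficiency per well against the sense-control
    mean and averages those.  With *reference* given, a
    ``relative_level`` column rescaled to that construct (= 1) is added.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns {missing}")
    ratios = plate.apply(
        lambda row: relative_luminescence(
            LuminescenceRecord(
                construct_id=row["construct_id"],
                fluc_raw=row["fluc"],
                rluc_raw=row["rluc"],
                fluc_background=row["fluc_bg"],
                rluc_background=row["rluc_bg"],
            )
        ),
        axis=1,
    )
    df = plate.assign(ratio=ratios)
    means = df.groupby("construct_id")["ratio"].mean()
    if sense_control not in means.index:
        raise ValueError(f"sense control {sense_control!r} not in table")
    control_mean = means[sense_control]
    if per_replicate:
        eff = (
            df.assign(
                eff=df["ratio"].map(
                    lambda x: readthrough_efficiency(x, control_mean)
                )
            )
            .groupby("construct_id")["eff"]
            .mean()
        )
    else:
        eff = means.map(lambda m: readthrough_efficiency(m, control_mean))
    out = pd.DataFrame(
        {
            "construct_id": eff.index,
            "mean_ratio": means[eff.index].to_numpy(),
            "efficiency_percent": eff.to_numpy(),
        }
    ).reset_index(drop=True)
    if reference is not None:
        levels = relative_readthrough_level(
            dict(zip(out["construct_id"], out["efficiency_percent"])), reference
        )
        out["relative_level"] = out["construct_id"].map(levels)
    return out
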