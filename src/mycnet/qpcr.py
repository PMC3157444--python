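"""TaqMan low-density-array CT preprocessing.

Raw qPCR threshold cycles (CT) from miRNA array cards are censored at 35
cycles, normalized per sample against the U6 small nuclear RNA internal
control (ΔCT = CT_miRNA − CT_U6; greater ΔCT means lower expression),
filtered for detection (minimum ΔCT below a cutoff), and optionally
converted to absolute copies per cell via a standard-curve-derived formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CT_CEILING = 35.0

#: input cell values treated as "undetected" when parsing CT tables
UNDETECTED_MARKERS = {"", "na", "nan", "undetermined", "undetected"}


@dataclass
class CtMatrix:
    """miRNA × sample matrix of raw or censored CT cycles.

    NaN entries mean "undetected". ``control_id`` names the internal-control
    row (U6 by convention) that ΔCT normalization subtracts.
    """

    values: pd.DataFrame
    control_id: str = "U6"
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.control_id not in self.values.index:
            raise ValueError(
                f"control row {self.control_id!r} missing from CT matrix"
            )

    @property
    def mirnas(self) -> list[str]:
        return [m for m in self.values.index if m != self.control_id]


@dataclass
class DeltaCtMatrix:
    """miRNA × sample matrix of U6-normalized CT (ΔCT, cycles).

    The control row is excluded. Greater ΔCT = lower miRNA expression.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)


def read_ct_table(path, control_id: str = "U6",
                  sample_groups: dict[str, str] | None = None) -> CtMatrix:
    """Read a TSV CT table (miRNA ids in first column, samples in header).

    Cells that are empty, 'NA', 'NaN', 'Undetermined' or 'Undetected'
    (case-insensitive) are parsed as undetected (NaN) and later censored
    to the 35-cycle ceiling.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    parsed = df.map(
        lambda v: np.nan
        if v is None or str(v).strip().lower() in UNDETECTED_MARKERS
        else float(v)
    ).astype(float)
    return CtMatrix(parsed, control_id=control_id,
                    sample_groups=dict(sample_groups or {}))


def censor_ct(raw: CtMatrix, ceiling: float = CT_CEILING) -> CtMatrix:
    """Censor undetected and high-CT entries to the detection ceiling.

    Every undetected (NaN) entry and every entry above ``ceiling`` is set
    to exactly ``ceiling``; everything else is unchanged. Idempotent.
    """
    vals = raw.values.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("negative CT values are not physical")
    out = raw.values.copy()
    arr = out.to_numpy(dtype=float)
    arr[np.isnan(arr) | (arr > ceiling)] = ceiling
    out.iloc[:, :] = arr
    return replace(raw, values=out)


def normalize_delta_ct(censored: CtMatrix) -> DeltaCtMatrix:
    """Per-sample ΔCT: subtract the control (U6) row from every miRNA row."""
    control = censored.values.loc[censored.control_id]
    missing = control.index[control.isna()]
    if len(missing):
        raise ValueError(
            f"control {censored.control_id!r} undetected in sample(s): "
            + ", ".join(map(str, missing))
        )
    dct = censored.values.drop(index=censored.control_id).sub(control, axis=1)
    return DeltaCtMatrix(dct, sample_groups=dict(censored.sample_groups))


def detection_filter(dct: DeltaCtMatrix, cutoff: float = 10.0,
                     scope: str = "any_sample") -> DeltaCtMatrix:
    """Keep miRNAs whose minimum ΔCT is strictly below ``cutoff``.

    ``scope="any_sample"`` (default) takes the minimum over all samples;
    ``scope="all_groups"`` requires the within-group minimum to clear the
    cutoff in every group.
    """
    if scope == "any_sample":
        keep = dct.values.min(axis=1) < cutoff
    elif scope == "all_groups":
        groups = pd.Series(dct.sample_groups)
        keep = pd.Series(True, index=dct.values.index)
        for g in groups.unique():
            cols = groups.index[groups == g]
            keep &= dct.values[cols].min(axis=1) < cutoff
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = dct.values.loc[keep]
    log.info("detection filter (ΔCT<%g): %d of %d miRNAs detected",
             cutoff, len(out), len(dct.values))
    return DeltaCtMatrix(out, sample_groups=dict(dct.sample_groups))


def copy_number(ct):
    """Copies per cell from a censored raw CT value.

    copies = 10**((40 − CT)/3.34) / 22, the lin-4 standard-curve
    calibration for cells holding ~30 pg total RNA. Strictly decreasing
    in CT; a 3.34-cycle decrease is a ten-fold increase in copies.

    Accepts scalars or arrays; CT must lie in (0, 40].
    """
    arr = np.asarray(ct, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 40):
        raise ValueError("CT must lie in (0, 40]")
    out = 10.0 ** ((40.0 - arr) / 3.34) / 22.0
    return out if out.ndim else float(out)
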