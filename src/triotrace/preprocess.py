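"""Peak-table screening and normalization.

The screening step mirrors the interquartile-range denoising used on GC-MS
peak tables: analytes whose across-sample IQR is exactly zero carry no
information and are always dropped; an optional quantile cut additionally
removes the lowest-spread fraction of the remaining analytes. Internal
standard normalization divides every sample by its internal-standard peak,
and half-minimum imputation handles left-censored missingness.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .tables import PeakTable, ValidationError

__all__ = [
    "DenoiseReport",
    "iqr_denoise",
    "normalize_internal_standard",
    "impute_missing",
    "NormalizationError",
    "ImputationError",
]


class NormalizationError(ValueError):
    pass


class ImputationError(ValueError):
    pass


@dataclasses.dataclass
class DenoiseReport:
    """What the IQR screen did: counts, dropped ids and the threshold used.

    ``threshold_used`` is the IQR value below which (strictly) analytes were
    dropped; IQRs are type-7 (linear interpolation) quartiles, recorded here
    so the screen is reproducible.
    """

    n_input_peaks: int
    n_retained: int
    dropped_ids: list[str]
    threshold_used: float
    quantile_cut: float

    def __post_init__(self) -> None:
        assert self.n_retained + len(self.dropped_ids) == self.n_input_peaks


def _iqr(values: pd.DataFrame) -> pd.Series:
    arr = values.to_numpy(dtype=float)
    q75 = np.nanpercentile(arr, 75, axis=1)
    q25 = np.nanpercentile(arr, 25, axis=1)
    return pd.Series(q75 - q25, index=values.index)


def iqr_denoise(
    table: PeakTable, quantile_cut: float = 0.0, threshold: float | None = None
) -> tuple[PeakTable, DenoiseReport]:
    """Drop zero-IQR analytes, then the lowest ``quantile_cut`` of the rest.

    Analytes with identical intensity in every sample (IQR == 0) are removed
    unconditionally. Among the remaining analytes, those whose IQR falls
    strictly below the ``quantile_cut`` quantile of the remaining IQR
    distribution are also removed. Analyte order is preserved. Passing an
    absolute ``threshold`` (e.g. a previous report's ``threshold_used``)
    bypasses the quantile and makes the screen idempotent.
    """
    if not 0.0 <= quantile_cut < 1.0:
        raise ValueError("quantile_cut must be in [0, 1)")
    if len(table.sample_ids) < 4:
        raise ValueError("IQR denoising needs at least 4 samples")
    iqr = _iqr(table.values)
    nonzero = iqr[iqr > 0]
    if threshold is None:
        threshold = 0.0
        if quantile_cut > 0 and len(nonzero):
            threshold = float(np.quantile(nonzero.to_numpy(), quantile_cut))
    keep = iqr.index[(iqr > 0) & (iqr >= threshold)]
    dropped = [a for a in table.analyte_ids if a not in set(keep)]
    report = DenoiseReport(
        n_input_peaks=len(table.analyte_ids),
        n_retained=len(keep),
        dropped_ids=dropped,
        threshold_used=threshold,
        quantile_cut=quantile_cut,
    )
    return table.subset(list(keep)), report


def normalize_internal_standard(table: PeakTable, is_id: str) -> PeakTable:
    """Divide each sample by its internal-standard intensity.

    The internal-standard analyte itself is removed from the output. A zero
    or missing internal-standard intensity in any sample is an error (named
    in the message) — there is no sensible scale for that run.
    """
    if is_id not in table.values.index:
        raise NormalizationError(f"internal standard {is_id!r} not in table")
    is_row = table.values.loc[is_id]
    bad = [s for s in table.sample_ids if not is_row[s] > 0]
    if bad:
        raise NormalizationError(
            f"internal standard {is_id!r} missing or non-positive in samples: {bad}"
        )
    rest = [a for a in table.analyte_ids if a != is_id]
    out = table.subset(rest)
    return dataclasses.replace(out, values=out.values.div(is_row, axis=1))


def impute_missing(table: PeakTable, method: str = "half_min") -> PeakTable:
    """Impute missing cells.

    ``half_min`` replaces each missing cell with half of that analyte's
    minimum observed intensity — the standard treatment for left-censored
    GC-MS missingness. ``none`` leaves the table untouched. An analyte with
    no observed value at all cannot be imputed and raises.
    """
    if method not in ("half_min", "none"):
        raise ValueError(f"unknown imputation method {method!r}")
    vals = table.values
    all_missing = vals.index[vals.isna().all(axis=1)]
    if len(all_missing) and method == "half_min":
        raise ImputationError(f"analytes with all values missing: {list(all_missing)}")
    if method == "none" or not vals.isna().any().any():
        return table
    half_min = vals.min(axis=1, skipna=True) / 2.0
    filled = vals.apply(lambda col: col.fillna(half_min))
    return dataclasses.replace(table, values=filled)
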