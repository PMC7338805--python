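"""Western-blot band quantification relative to a reference sample.

Lane signal is the sum of band intensities divided by the total-protein
loading signal (stain-free); each lane is then expressed as a percentage
of the reference sample's mean signal, and replicate percentages are
summarised per sample. Group differences are assessed with a two-sided
Student's t-test (pooled variance, matching equal-n blot designs;
Welch is available via ``welch=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class LaneQuant:
    sample: str
    replicate: str
    band_intensities: tuple[float, ...]
    loading_total: float

    def __post_init__(self) -> None:
        if self.loading_total <= 0:
            raise ValueError("loading_total must be positive")
        if any(b < 0 for b in self.band_intensities):
            raise ValueError("band intensities must be non-negative")

    @property
    def signal(self) -> float:
        return sum(self.band_intensities) / self.loading_total


def relative_quant(lanes: list[LaneQuant], reference_sample: str) -> pd.DataFrame:
    """Per-sample mean +/- SD of loading-normalized signal, in percent of reference.

    The reference sample's own mean is 100% by construction.
    """
    ref_signals = [l.signal for l in lanes if l.sample == reference_sample]
    if not ref_signals:
        raise ValueError(f"reference sample {reference_sample!r} has no lanes")
    ref_mean = float(np.mean(ref_signals))
    df = pd.DataFrame(
        {
            "sample": [l.sample for l in lanes],
            "replicate": [l.replicate for l in lanes],
            "percent": [100.0 * l.signal / ref_mean for l in lanes],
        }
    )
    out = df.groupby("sample", sort=False)["percent"].agg(
        mean_percent="mean", sd_percent=lambda x: x.std(ddof=1), n="count"
    )
    return out.reset_index()


def lanes_from_frame(df: pd.DataFrame) -> list[LaneQuant]:
    """Build lanes from a TSV-style frame: sample, replicate, band columns, loading_total."""
    band_cols = [c for c in df.columns if c.startswith("band")]
    return [
        LaneQuant(
            sample=str(row["sample"]),
            replicate=str(row["replicate"]),
            band_intensities=tuple(
                float(row[c]) for c in band_cols if pd.notna(row[c])
            ),
            loading_total=float(row["loading_total"]),
        )
        for _, row in df.iterrows()
    ]


def two_group_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided t-test; identical zero-variance groups give (0, 1) by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
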