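"""Test-retest repeatability of the deep-plexus metrics.

Intra-session repeatability compares two scans taken minutes apart in the
same visit; inter-session reproducibility compares the first scans of two
visits within two weeks.  Agreement is summarised by the intraclass
correlation coefficient.  The default model is ICC(2,1): two-way
random-effects, absolute agreement, single measure — the standard choice
for test-retest of a single device — with an F-based 95% confidence
interval.  An average-measure variant (ICC(2,k)) is available via
``measure="average"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import pingouin as pg

__all__ = [
    "IccResult",
    "compute_icc",
    "SESSION_PAIRS",
    "InsufficientDataError",
    "DegenerateVarianceError",
]

SESSION_PAIRS = {
    "intra": ("visit1_scan1", "visit1_scan2"),
    "inter": ("visit1_scan1", "visit2_scan1"),
}

MIN_COMPLETE_PAIRS = 5


class InsufficientDataError(ValueError):
    """Fewer complete measurement pairs than required."""


class DegenerateVarianceError(ValueError):
    """All measurements identical; the ICC is undefined."""


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model_label: str
    n_eyes: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.icc <= self.ci_high:
            raise ValueError("CI must bracket the ICC estimate")
        if self.icc > 1:
            raise ValueError("ICC cannot exceed 1")


def compute_icc(
    data: pd.DataFrame,
    metric_name: str,
    pair: str = "intra",
    measure: str = "single",
) -> IccResult:
    """ICC of one metric between the two sessions of the chosen pair.

    ``data`` is long-format with columns
    ``eye_id, session_label, metric_name, value`` (one randomly selected
    eye per subject, so eyes are independent targets).  ``pair`` selects
    intra-session (scan 1 vs scan 2 of visit 1) or inter-session (visit 1
    vs visit 2 first scans).
    """
    if pair not in SESSION_PAIRS:
        raise ValueError(f"pair must be one of {sorted(SESSION_PAIRS)}, got {pair!r}")
    if measure not in ("single", "average"):
        raise ValueError("measure must be 'single' or 'average'")
    sessions = SESSION_PAIRS[pair]
    sub = data[(data["metric_name"] == metric_name) & data["session_label"].isin(sessions)]
    wide = sub.pivot_table(index="eye_id", columns="session_label", values="value").dropna()
    if len(wide) < MIN_COMPLETE_PAIRS or wide.shape[1] < 2:
        raise InsufficientDataError(
            f"need >= {MIN_COMPLETE_PAIRS} eyes with complete {sessions} pairs, "
            f"got {len(wide)}"
        )
    values = wide[list(sessions)]
    if values.to_numpy().std() < 1e-12:
        raise DegenerateVarianceError("all measurements identical; ICC undefined")

    long = values.reset_index().melt(
        id_vars="eye_id", var_name="session_label", value_name="value"
    )
    with warnings.catch_warnings():
        # exact agreement (MSE == 0) trips a harmless division warning
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="eye_id", raters="session_label", ratings="value"
        ).set_index("Type")
    row = table.loc["ICC(A,1)" if measure == "single" else "ICC(A,k)"]
    ci_low, ci_high = (float(v) for v in row["CI95"])
    icc = min(float(row["ICC"]), 1.0)
    label = (
        "ICC(2,1) two-way random effects, absolute agreement, single measure"
        if measure == "single"
        else "ICC(2,k) two-way random effects, absolute agreement, average measure"
    )
    return IccResult(
        icc=icc,
        ci_low=min(ci_low, icc),
        ci_high=max(ci_high, icc),
        model_label=label,
        n_eyes=int(len(wide)),
    )
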