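"""Shape-based quality control of estimated voxel HRFs.

Noisy voxels yield FIR estimates that violate basic hemodynamic priors.
After max-normalization, a voxel is rejected when any of three rules fires:

* ONSET — the response does not start near zero: ``|h(0)| > 0.3``;
* TAIL — the response has not returned to baseline late: the maximum over
  samples later than 12 s exceeds 0.4;
* UNDERSHOOT — the normalized undershoot is implausibly deep: the minimum
  over all samples is below -1.

Thresholds are configurable; the defaults encode the prior that a genuine
BOLD impulse response starts at zero, peaks around 5-6 s and settles back
to baseline with at most a modest undershoot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectionReport", "normalize_hrf", "apply_selection_criterion",
           "select_voxels"]

ALL_RULES = ("ONSET", "TAIL", "UNDERSHOOT")


@dataclass
class SelectionReport:
    voxel_id: int
    passed: bool
    violated_rules: tuple
    normalized_h: np.ndarray | None

    def __post_init__(self):
        if self.passed != (len(self.violated_rules) == 0):
            raise ValueError("passed must equal 'no violated rules'")


def normalize_hrf(h: np.ndarray) -> np.ndarray:
    """Divide by the maximum so that the peak equals exactly 1."""
    h = np.asarray(h, dtype=float)
    m = h.max()
    if m <= 0:
        raise ValueError("cannot normalize an HRF with nonpositive maximum")
    return h / m


def apply_selection_criterion(
    h_norm: np.ndarray,
    tr: float,
    voxel_id: int = 0,
    onset_threshold: float = 0.3,
    tail_threshold: float = 0.4,
    tail_start: float = 12.0,
    undershoot_threshold: float = -1.0,
) -> SelectionReport:
    """Evaluate the three rejection rules on a max-normalized HRF.

    The TAIL rule looks at samples with ``i * tr > tail_start`` (strict);
    if the HRF is too short to contain any such sample the rule passes
    vacuously, with a warning.
    """
    h_norm = np.asarray(h_norm, dtype=float)
    violated = []
    if abs(h_norm[0]) > onset_threshold:
        violated.append("ONSET")
    times = np.arange(len(h_norm)) * tr
    tail = times > tail_start
    if not tail.any():
        warnings.warn(
            f"HRF support ({times[-1]:g} s) ends before the tail window "
            f"(> {tail_start:g} s); TAIL rule passes vacuously",
            stacklevel=2,
        )
    elif h_norm[tail].max() > tail_threshold:
        violated.append("TAIL")
    if h_norm.min() < undershoot_threshold:
        violated.append("UNDERSHOOT")
    return SelectionReport(
        voxel_id=voxel_id,
        passed=len(violated) == 0,
        violated_rules=tuple(violated),
        normalized_h=h_norm,
    )


def select_voxels(
    H: np.ndarray, tr: float, voxel_ids=None, **thresholds
) -> list[SelectionReport]:
    """Normalize and screen a bank of HRFs (columns of the L x V matrix H).

    Voxels whose estimate has a nonpositive maximum cannot be normalized;
    they are reported as failing every rule rather than raising, so a bad
    voxel never aborts a batch.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if voxel_ids is None:
        voxel_ids = np.arange(H.shape[1])
    reports = []
    for v, vid in zip(range(H.shape[1]), voxel_ids):
        h = H[:, v]
        if not np.all(np.isfinite(h)) or h.max() <= 0:
            reports.append(SelectionReport(
                voxel_id=vid, passed=False, violated_rules=ALL_RULES,
                normalized_h=None,
            ))
            continue
        reports.append(
            apply_selection_criterion(normalize_hrf(h), tr, voxel_id=vid,
                                      **thresholds)
        )
    return reports


def reports_to_frame(reports: list[SelectionReport]) -> pd.DataFrame:
    """Tabulate selection reports for writing as a delimited file."""
    return pd.DataFrame(
        {
            "voxel_id": [r.voxel_id for r in reports],
            "passed": [r.passed for r in reports],
            "violated_rules": ["|".join(r.violated_rules) for r in reports],
        }
    )
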