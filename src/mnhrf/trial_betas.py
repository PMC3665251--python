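"""Single-trial response amplitudes by the least-squares-separate (LS-S) scheme.

In rapid designs, one regressor per trial in a single GLM is heavily
collinear. LS-S instead fits one small GLM per trial: the trial of interest
is one regressor (its onset indicator convolved with the HRF), all other
trials are collapsed into a single nuisance regressor, and the drift basis
is optionally appended. The coefficient on the interest regressor is that
trial's beta; repeating over trials and voxels yields the trials x voxels
feature matrix for decoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSet, EventSchedule, build_stimulus_matrix

__all__ = ["TrialBetaMatrix", "build_lss_design", "estimate_trial_betas"]

logger = logging.getLogger(__name__)


@dataclass
class TrialBetaMatrix:
    """Trials x voxels single-trial amplitudes with condition labels."""

    betas: np.ndarray
    labels: np.ndarray
    run_ids: np.ndarray
    hrf_source: str
    lff_included: bool

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def drop_nonfinite(self) -> "TrialBetaMatrix":
        """Drop trials with any non-finite beta (failed fits are logged,
        never filled)."""
        ok = np.all(np.isfinite(self.betas), axis=1)
        return TrialBetaMatrix(
            betas=self.betas[ok],
            labels=self.labels[ok],
            run_ids=self.run_ids[ok],
            hrf_source=self.hrf_source,
            lff_included=self.lff_included,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.betas, columns=[f"voxel_{v}" for v in range(self.n_voxels)]
        )
        df.insert(0, "run", self.run_ids)
        df.insert(1, "trial_type", self.labels)
        return df


def _convolve_sticks(stick: np.ndarray, h: np.ndarray) -> np.ndarray:
    return np.convolve(stick, h)[: len(stick)]


def build_lss_design(
    schedule: EventSchedule,
    trial_index: int,
    h: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> np.ndarray:
    """LS-S design for one trial: [target | all-others | drift basis].

    Column 0 is the target trial's onset indicator convolved with the HRF
    ``h``; column 1 is the summed indicator of every other trial convolved
    with ``h`` (all-zero for a single-trial schedule, flagged by the
    caller); the remaining columns are the drift basis if given.
    """
    if not 0 <= trial_index < schedule.n_trials:
        raise IndexError(
            f"trial_index {trial_index} out of range for {schedule.n_trials} trials"
        )
    vols = schedule.onset_volumes()
    N = schedule.run_length
    target = np.zeros(N)
    target[vols[trial_index]] = 1.0
    others = np.zeros(N)
    mask = np.ones(schedule.n_trials, dtype=bool)
    mask[trial_index] = False
    np.add.at(others, vols[mask], 1.0)
    cols = [_convolve_sticks(target, h), _convolve_sticks(others, h)]
    if nuisance is not None:
        cols.extend(nuisance.T)
    return np.column_stack(cols)


def estimate_trial_betas(
    Y,
    schedules,
    hrfs,
    lff_included: bool = True,
    nuisance_bases=None,
    hrf_source: str | None = None,
) -> TrialBetaMatrix:
    """LS-S betas for every trial and voxel, runs fitted independently.

    Parameters
    ----------
    Y
        One N x V data matrix per run (a single matrix is accepted for a
        single run).
    schedules
        One EventSchedule per run.
    hrfs
        Either a single length-L canonical HRF applied to every voxel, or
        an L x V array of voxel-specific kernels (estimated on a held-out
        run and treated as fixed here).
    lff_included
        Append the orthonormal Legendre drift basis to every per-trial GLM.
    nuisance_bases
        Optional per-run drift bases; built from each run's length when
        omitted and ``lff_included`` is true.

    A rank-deficient per-trial design (e.g. duplicated onsets) marks that
    trial's betas as missing (NaN) and logs it; use
    :meth:`TrialBetaMatrix.drop_nonfinite` before decoding.
    """
    if isinstance(Y, np.ndarray):
        Y = [Y]
    if isinstance(schedules, EventSchedule):
        schedules = [schedules]
    if len(Y) != len(schedules):
        raise ValueError("one data matrix per schedule is required")

    hrfs = np.asarray(hrfs, dtype=float)
    voxel_specific = hrfs.ndim == 2
    n_vox = Y[0].shape[1]
    if voxel_specific and hrfs.shape[1] != n_vox:
        raise ValueError(
            f"got {hrfs.shape[1]} voxel HRFs for {n_vox} voxels"
        )
    if hrf_source is None:
        hrf_source = "VOXEL_SPECIFIC" if voxel_specific else "CANONICAL"

    from .design import build_nuisance_basis

    beta_blocks, label_blocks, run_blocks = [], [], []
    for r, (Yr, sched) in enumerate(zip(Y, schedules)):
        if Yr.shape[0] != sched.run_length:
            raise ValueError(
                f"run {r}: data has {Yr.shape[0]} volumes, schedule says "
                f"{sched.run_length}"
            )
        if lff_included:
            P = (nuisance_bases[r] if nuisance_bases is not None
                 else build_nuisance_basis(sched.run_length))
        else:
            P = None
        T = sched.n_trials
        betas = np.full((T, n_vox), np.nan)
        kernels = hrfs.T if voxel_specific else [hrfs]
        for vi, h in enumerate(kernels):
            for t in range(T):
                Xd = build_lss_design(sched, t, h, nuisance=P)
                if sched.n_trials == 1 or not np.any(Xd[:, 1]):
                    logger.info("run %d trial %d: no other trials; "
                                "dropping the nuisance-trial regressor", r, t)
                    Xd = np.delete(Xd, 1, axis=1)
                if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
                    logger.warning(
                        "run %d trial %d: rank-deficient LS-S design; "
                        "betas set missing", r, t)
                    continue
                rhs = Yr[:, vi] if voxel_specific else Yr
                coef, *_ = np.linalg.lstsq(Xd, rhs, rcond=None)
                if voxel_specific:
                    betas[t, vi] = coef[0]
                else:
                    betas[t, :] = coef[0]
            if not voxel_specific:
                break
        beta_blocks.append(betas)
        label_blocks.append(np.asarray(sched.labels))
        run_blocks.append(np.full(T, r))

    return TrialBetaMatrix(
        betas=np.vstack(beta_blocks),
        labels=np.concatenate(label_blocks),
        run_ids=np.concatenate(run_blocks),
        hrf_source=hrf_source,
        lff_included=lff_included,
    )
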