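"""Design-side matrices for FIR deconvolution of event-related BOLD time series.

The measured signal in one run is modeled as ``y = S h + P b + eps`` where

* ``S`` (N x L) is the stimulus convolution matrix built from the trial onset
  indicator sequence, so that ``S @ h`` is the discrete convolution of the
  onsets with the length-L FIR hemodynamic response ``h``;
* ``P`` (N x B) is an orthonormal low-frequency drift basis (Legendre
  polynomials of degrees 0..3 by default);
* ``D`` ((L-2) x L) is the second-difference operator penalizing HRF
  roughness;
* ``C`` (L x L) is a diagonal 0/1 operator penalizing the HRF value at the
  onset sample and in the late tail (after ``t_base`` seconds), encoding the
  physiological prior that the response starts at zero and has returned to
  baseline by ~10 s after a brief stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

__all__ = [
    "EventSchedule",
    "DesignSet",
    "build_stimulus_matrix",
    "build_nuisance_basis",
    "build_second_difference",
    "build_tail_penalty",
]


@dataclass(frozen=True)
class EventSchedule:
    """Trial timeline of one fMRI run.

    Parameters
    ----------
    onsets
        Trial onset times in seconds from the first retained volume,
        sorted ascending, all nonnegative.
    durations
        Stimulus durations in seconds (one per trial).
    labels
        Condition label per trial.
    run_length
        Number of volumes N in the run.
    tr
        Repetition time (sampling interval) in seconds.
    """

    onsets: np.ndarray
    durations: np.ndarray
    labels: np.ndarray
    run_length: int
    tr: float

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "labels", labels)
        if onsets.ndim != 1:
            raise ValueError("onsets must be one-dimensional")
        if len(durations) != len(onsets) or len(labels) != len(onsets):
            raise ValueError("onsets, durations and labels must have equal length")
        if np.any(onsets < 0):
            raise ValueError("onsets must be nonnegative")
        if np.any(np.diff(onsets) < 0):
            raise ValueError("onsets must be sorted ascending")
        if self.run_length <= 0 or self.tr <= 0:
            raise ValueError("run_length and tr must be positive")
        end = self.run_length * self.tr
        if np.any(onsets + durations > end + 1e-9):
            raise ValueError(
                "timeline error: trial extends past the end of the run "
                f"(run covers [0, {end:g}) s)"
            )

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def onset_volumes(self) -> np.ndarray:
        """Onsets snapped to the nearest volume index."""
        return np.rint(self.onsets / self.tr).astype(int)

    def onset_indicator(self, duration_coding: bool = False) -> np.ndarray:
        """Length-N indicator of event occurrences on the volume grid.

        With ``duration_coding`` every volume covered by the stimulus
        duration is marked; by default only the onset volume is.
        Coincident events accumulate.
        """
        s = np.zeros(self.run_length)
        vols = self.onset_volumes()
        if np.any(vols >= self.run_length):
            raise ValueError("timeline error: onset outside the run after snapping")
        if duration_coding:
            n_samp = np.maximum(1, np.rint(self.durations / self.tr).astype(int))
            for v, k in zip(vols, n_samp):
                hi = min(v + k, self.run_length)
                s[v:hi] += 1.0
        else:
            np.add.at(s, vols, 1.0)
        return s

    @classmethod
    def from_events_table(
        cls, path_or_df, run_length: int, tr: float
    ) -> "EventSchedule":
        """Read a BIDS-dialect events table (columns onset, duration, trial_type)."""
        if isinstance(path_or_df, pd.DataFrame):
            df = path_or_df
        else:
            df = pd.read_csv(path_or_df, sep="\t")
        df = df.sort_values("onset", kind="stable")
        return cls(
            onsets=df["onset"].to_numpy(dtype=float),
            durations=df["duration"].to_numpy(dtype=float),
            labels=df["trial_type"].to_numpy(),
            run_length=run_length,
            tr=tr,
        )

    def to_events_table(self, path=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"onset": self.onsets, "duration": self.durations, "trial_type": self.labels}
        )
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def build_stimulus_matrix(
    schedule: EventSchedule,
    hrf_length_samples: int,
    duration_coding: bool = False,
) -> np.ndarray:
    """Stimulus convolution matrix S (N x L).

    Column k is the onset indicator shifted down by k samples and
    zero-padded, so ``S @ h`` equals the discrete convolution of the onset
    sequence with ``h`` truncated to N samples.
    """
    if hrf_length_samples < 1:
        raise ValueError("hrf_length_samples must be >= 1")
    if hrf_length_samples > schedule.run_length:
        raise ValueError(
            f"hrf_length_samples ({hrf_length_samples}) exceeds run length "
            f"({schedule.run_length} volumes)"
        )
    s = schedule.onset_indicator(duration_coding=duration_coding)
    first_row = np.zeros(hrf_length_samples)
    first_row[0] = s[0]
    return toeplitz(s, first_row)


def build_nuisance_basis(n_volumes: int, max_degree: int = 3) -> np.ndarray:
    """Orthonormal Legendre drift basis P (N x (max_degree+1)).

    Legendre polynomials of degrees 0..max_degree are evaluated on an even
    grid spanning [-1, 1] and then orthonormalized (QR), because discrete
    sampling breaks their exact orthogonality. ``P.T @ P`` is the identity
    to machine precision, so ``P @ P.T`` is an orthogonal projector onto
    the drift subspace.
    """
    if n_volumes <= max_degree + 1:
        raise ValueError(
            f"n_volumes ({n_volumes}) must exceed max_degree + 1 ({max_degree + 1})"
        )
    x = np.linspace(-1.0, 1.0, n_volumes)
    V = np.polynomial.legendre.legvander(x, max_degree)
    Q, R = np.linalg.qr(V)
    # fix signs so each column correlates positively with the raw polynomial
    Q = Q * np.sign(np.diag(R))
    return Q


def build_second_difference(hrf_length_samples: int) -> np.ndarray:
    """Second-difference (discrete curvature) operator D ((L-2) x L).

    Row i carries the stencil (1, -2, 1) at columns i, i+1, i+2; ``D @ h``
    vanishes on any affine sequence.
    """
    L = hrf_length_samples
    if L < 3:
        raise ValueError("hrf_length_samples must be >= 3 (no curvature to penalize)")
    D = np.zeros((L - 2, L))
    idx = np.arange(L - 2)
    D[idx, idx] = 1.0
    D[idx, idx + 1] = -2.0
    D[idx, idx + 2] = 1.0
    return D


def build_tail_penalty(
    hrf_length_samples: int, tr: float, t_base: float = 10.0
) -> np.ndarray:
    """Diagonal onset+tail shape penalty C (L x L).

    Diagonal entries are 1 at index 0 (the HRF should start at zero) and at
    every index i with ``i * tr > t_base`` (the response should have
    returned to baseline), 0 elsewhere, so
    ``||C h||^2 = h(0)^2 + sum_{i*tr > t_base} h(i)^2``.
    """
    L = hrf_length_samples
    if L < 2:
        raise ValueError("hrf_length_samples must be >= 2")
    if t_base < 0:
        raise ValueError("t_base must be nonnegative")
    diag = np.zeros(L)
    diag[0] = 1.0
    times = np.arange(L) * tr
    tail = times > t_base
    if not tail.any():
        warnings.warn(
            f"t_base={t_base} s lies beyond the HRF support "
            f"({(L - 1) * tr} s); tail penalty is empty, only the onset term remains",
            stacklevel=2,
        )
    diag[tail] = 1.0
    return np.diag(diag)


@dataclass
class DesignSet:
    """All design-side matrices for one run: S, P, D, C."""

    S: np.ndarray
    P: np.ndarray
    D: np.ndarray
    C: np.ndarray
    L: int
    tr: float
    t_base: float = 10.0
    schedule: EventSchedule | None = field(default=None, repr=False)

    @classmethod
    def from_schedule(
        cls,
        schedule: EventSchedule,
        hrf_length_samples: int,
        t_base: float = 10.0,
        drift_degree: int = 3,
        duration_coding: bool = False,
    ) -> "DesignSet":
        S = build_stimulus_matrix(schedule, hrf_length_samples, duration_coding)
        P = build_nuisance_basis(schedule.run_length, drift_degree)
        D = build_second_difference(hrf_length_samples)
        C = build_tail_penalty(hrf_length_samples, schedule.tr, t_base)
        return cls(
            S=S, P=P, D=D, C=C,
            L=hrf_length_samples, tr=schedule.tr, t_base=t_base,
            schedule=schedule,
        )

    @property
    def n_volumes(self) -> int:
        return self.S.shape[0]
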