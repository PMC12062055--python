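"""Exact dynamic mode decomposition of incidence panels.

Given annual snapshots x_1..x_m (one rate per county), form the shifted
pair X1 = [x_1..x_{m-1}], X2 = [x_2..x_m] and assume x_{k+1} ~ A x_k. The
best-fit propagator A = X2 X1^+ is never materialized (n ~ 1000 counties);
instead a reduced-rank SVD X1 ~ U S V* yields the r x r projection

    A_tilde = U* X2 V S^{-1},

whose eigenpairs (lambda, w) give the DMD eigenvalues and, lifted through
Phi = X2 V S^{-1} W, the spatial modes. Each mode is one complex loading per
county evolving geometrically in its eigenvalue: |lambda| < 1 decays,
arg(lambda) is the oscillation frequency per year. Amplitudes b solve the
least-squares fit Phi b ~ x_1, so the k-step state is

    x_k ~ Re( Phi diag(lambda)^(k-1) b ).

Diagnostics mirror standard practice for rate panels: a rank sweep (holdout
RMSE and retained singular-value energy per truncation rank), the eigenvalue
spectrum relative to the unit circle, and a per-county table of dominant
steady-mode magnitudes keyed by FIPS for choropleth joins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    NoSteadyModeError,
    RankError,
    ValidationError,
)
from .io_panel import IncidencePanel

__all__ = [
    "SnapshotPair",
    "DMDModel",
    "build_snapshots",
    "fit",
    "predict",
    "reconstruction_rmse",
    "rank_sweep",
    "eigen_spectrum",
    "dominant_mode_table",
]


@dataclass
class SnapshotPair:
    """Time-shifted snapshot matrices X1 (x_1..x_{m-1}) and X2 (x_2..x_m)."""

    X1: np.ndarray = field(repr=False)
    X2: np.ndarray = field(repr=False)
    counties: list[str]
    years: list[int]  # the m training years

    def __post_init__(self):
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        if self.X1.shape != self.X2.shape or self.X1.ndim != 2:
            raise ValidationError("X1 and X2 must be equal-shape 2-D matrices")
        if self.X1.shape[1] < 1:
            raise InsufficientDataError("need at least 2 snapshots")
        # Shift consistency: X1 columns 2.. equal X2 columns ..-1.
        if self.X1.shape[1] > 1 and not np.array_equal(
            self.X1[:, 1:], self.X2[:, :-1]
        ):
            raise ValidationError("snapshot pair is not a one-step shift")

    @property
    def n(self) -> int:
        return self.X1.shape[0]

    @property
    def m(self) -> int:
        """Total snapshot count (columns of X1 plus the final state)."""
        return self.X1.shape[1] + 1

    def snapshot(self, k: int) -> np.ndarray:
        """State x_k, 1-based."""
        if not 1 <= k <= self.m:
            raise ValidationError(f"snapshot index {k} outside 1..{self.m}")
        return self.X1[:, k - 1] if k < self.m else self.X2[:, -1]


@dataclass
class DMDModel:
    """Fitted decomposition at rank ``r``.

    ``Phi`` columns are unit-norm modes aligned with ``eigenvalues`` (sorted
    by magnitude descending, phase ascending); ``amplitudes`` absorb the mode
    scale. ``singular_values_full`` keeps the entire spectrum of X1 for
    energy-ratio diagnostics.
    """

    r: int
    U: np.ndarray = field(repr=False)
    S: np.ndarray
    V: np.ndarray = field(repr=False)
    A_tilde: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray
    W: np.ndarray = field(repr=False)
    Phi: np.ndarray = field(repr=False)
    amplitudes: np.ndarray
    m: int
    counties: list[str]
    numerical_rank: int
    singular_values_full: np.ndarray = field(repr=False)

    def energy_ratio(self, r: int | None = None) -> float:
        """Fraction of squared singular-value mass retained at rank r."""
        r = self.r if r is None else r
        s2 = self.singular_values_full**2
        return float(s2[:r].sum() / s2.sum())


def build_snapshots(
    panel: IncidencePanel, train_years: tuple[int, int] | None = None
) -> SnapshotPair:
    """Restrict a complete panel to the training window and form (X1, X2)."""
    if not panel.is_complete:
        raise ValidationError("panel has missing entries; filter before DMD")
    sub = panel if train_years is None else panel.restrict_years(*train_years)
    if sub.n_years < 2:
        raise InsufficientDataError(
            f"need >= 2 snapshots, got {sub.n_years}"
        )
    X = sub.values
    return SnapshotPair(
        X1=X[:, :-1], X2=X[:, 1:], counties=list(sub.counties),
        years=list(sub.years),
    )


def _numerical_rank(s: np.ndarray, shape: tuple[int, int]) -> int:
    if s.size == 0 or s[0] == 0:
        return 0
    tol = max(shape) * np.finfo(float).eps * s[0]
    return int((s > tol).sum())


def _sort_order(lam: np.ndarray) -> np.ndarray:
    # |lambda| descending, then phase ascending (deterministic tie-break).
    return np.lexsort((np.angle(lam), -np.abs(lam)))


def fit(snapshots: SnapshotPair, r: int | str = "full") -> DMDModel:
    """Exact DMD of a snapshot pair at truncation rank ``r``.

    ``r="full"`` uses the numerical rank of X1 (singular values above
    ``max(n, m-1) * eps * sigma_1``). Requesting a rank beyond the numerical
    rank raises :class:`RankError` reporting the attainable rank.
    """
    X1, X2 = snapshots.X1, snapshots.X2
    U_full, s_full, Vh_full = np.linalg.svd(X1, full_matrices=False)
    num_rank = _numerical_rank(s_full, X1.shape)
    if num_rank == 0:
        raise DegenerateInputError("X1 is numerically zero; nothing to decompose")
    if r == "full":
        r_use = num_rank
    else:
        r_use = int(r)
        if r_use < 1:
            raise ValidationError(f"rank must be >= 1, got {r_use}")
        if r_use > num_rank:
            raise RankError(r_use, num_rank)

    U = U_full[:, :r_use]
    S = s_full[:r_use]
    V = Vh_full[:r_use].T
    A_tilde = (U.T @ X2 @ V) / S  # right-divide = post-multiply by S^{-1}

    lam, W = np.linalg.eig(A_tilde)
    order = _sort_order(lam)
    lam, W = lam[order], W[:, order]

    Phi = ((X2 @ V) / S) @ W
    norms = np.linalg.norm(Phi, axis=0)
    norms[norms == 0] = 1.0
    Phi = Phi / norms

    x1 = X1[:, 0]
    b, *_ = np.linalg.lstsq(Phi, x1.astype(complex), rcond=None)

    return DMDModel(
        r=r_use, U=U, S=S, V=V, A_tilde=A_tilde, eigenvalues=lam, W=W,
        Phi=Phi, amplitudes=b, m=snapshots.m, counties=list(snapshots.counties),
        numerical_rank=num_rank, singular_values_full=s_full,
    )


def predict(model: DMDModel, k: int) -> np.ndarray:
    """Real-valued state estimate x_k = Re(Phi diag(lambda)^(k-1) b), k >= 1.

    k = 1..m reconstructs the training snapshots (least-squares projection
    onto the mode span); k = m + 1 is the one-step-ahead forecast.
    """
    if k < 1:
        raise ValidationError(f"step index must be >= 1, got {k}")
    coeff = model.amplitudes * model.eigenvalues ** (k - 1)
    return (model.Phi @ coeff).real


def reconstruction_rmse(model: DMDModel, snapshots: SnapshotPair) -> float:
    """In-sample RMSE of the modal reconstruction over all m snapshots."""
    errs = [
        predict(model, k) - snapshots.snapshot(k)
        for k in range(1, snapshots.m + 1)
    ]
    return float(np.sqrt(np.mean(np.square(errs))))


def rank_sweep(
    snapshots: SnapshotPair,
    holdout: np.ndarray,
    ranks: list[int] | None = None,
) -> pd.DataFrame:
    """Holdout RMSE and retained energy per truncation rank.

    For each rank, fits DMD on the pair, forecasts the step after the last
    training snapshot (k = m + 1), scores RMSE against ``holdout``, and
    records energy_ratio(r) = sum_{i<=r} s_i^2 / sum_i s_i^2.
    """
    holdout = np.asarray(holdout, dtype=float)
    if holdout.shape != (snapshots.n,):
        raise ValidationError("holdout length must equal county count")
    s_full = np.linalg.svd(snapshots.X1, compute_uv=False)
    num_rank = _numerical_rank(s_full, snapshots.X1.shape)
    if ranks is None:
        ranks = list(range(1, num_rank + 1))
    rows = []
    for r in ranks:
        try:
            model = fit(snapshots, r)
        except (RankError, ValidationError) as exc:
            raise type(exc)(f"rank {r}: {exc}") from exc
        pred = predict(model, snapshots.m + 1)
        rmse = float(np.sqrt(np.mean((pred - holdout) ** 2)))
        rows.append({"rank": r, "rmse": rmse, "energy_ratio": model.energy_ratio(r)})
    return pd.DataFrame(rows)


def eigen_spectrum(model: DMDModel) -> pd.DataFrame:
    """Per-eigenvalue diagnostics relative to the unit circle.

    ``frequency = |arg lambda|`` (oscillation per year), ``growth =
    ln |lambda|`` (continuous-time growth rate); ``inside_unit_circle`` flags
    decaying modes (|lambda| < 1, boundary excluded).
    """
    lam = model.eigenvalues
    mag = np.abs(lam)
    with np.errstate(divide="ignore"):
        growth = np.log(mag)
    return pd.DataFrame(
        {
            "re": lam.real,
            "im": lam.imag,
            "magnitude": mag,
            "frequency": np.abs(np.angle(lam)),
            "growth": growth,
            "inside_unit_circle": mag < 1.0,
        }
    )


def dominant_mode_table(
    model: DMDModel,
    panel: IncidencePanel | None = None,
    freq_tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-county magnitude of the dominant steady (zero-frequency) mode.

    Among eigenvalues with |arg lambda| < ``freq_tol`` (the steady,
    non-oscillating modes) the one with the largest end-of-window amplitude
    |b_j| |lambda_j|^(m-1) is selected; its per-county loading magnitudes
    |phi_ij| are returned keyed by FIPS, ready to join onto county geometry.
    The selected eigenvalue is stored in ``DataFrame.attrs``.
    """
    lam = model.eigenvalues
    steady = np.where(np.abs(np.angle(lam)) < freq_tol)[0]
    if steady.size == 0:
        raise NoSteadyModeError(
            f"no eigenvalue with |arg lambda| < {freq_tol}; "
            "consider a looser freq_tol"
        )
    weight = np.abs(model.amplitudes[steady]) * np.abs(lam[steady]) ** (model.m - 1)
    j = steady[int(np.argmax(weight))]
    counties = model.counties if panel is None else panel.counties
    if len(counties) != model.Phi.shape[0]:
        raise ValidationError("panel county count does not match the model")
    out = pd.DataFrame(
        {"fips": counties, "magnitude": np.abs(model.Phi[:, j])}
    )
    out.attrs["eigenvalue"] = complex(lam[j])
    out.attrs["mode_index"] = int(j)
    return out
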