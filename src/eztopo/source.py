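"""EEG forward and inverse modelling: spherical lead field and sLORETA.

Forward model
-------------
Scalp potentials are modelled as ``phi = K J + c 1`` where ``K`` is the
lead field of an analytic concentric-shell spherical conductor (default
three shells: brain, skull, scalp).  For a dipole at radius ``b`` the
potential is expanded in Legendre series; the radial profile of each
degree ``n`` is obtained by solving the boundary-condition system
(continuity of potential and radial current at each interface, zero
current through the outer surface), so the solver works for any number
of shells.  An average-reference projector is applied to the rows of
``K``, which absorbs the arbitrary reference constant ``c``.

Inverse model
-------------
The minimum-norm estimate minimizes ``||phi - K J - c 1||^2 + alpha
||J||^2`` jointly over ``J`` and ``c``:

    J_hat = K^T (K K^T + alpha H)^+ H phi,      H = I - 11^T / N_E.

sLORETA standardizes ``J_hat`` by its resolution-based variance: with
``S = K^T (K K^T + alpha H)^+ K``, the standardized power of source
``l`` is ``J_l^T [S]_ll^{-1} J_l`` (the 3x3 diagonal block).  For
noiseless single-dipole data this has zero localization error for any
``alpha >= 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "HeadModel",
    "SourceModel",
    "default_montage",
    "make_source_grid",
    "make_parcellation",
    "build_lead_field",
    "minimum_norm_solve",
    "sloreta_standardize",
    "SLORETA",
    "parcellate",
]

# Idealized unit-sphere 10-20 positions (BESA spherical angles, degrees):
# theta signed from the vertex (negative = left), phi from the +x (right
# ear) axis toward the front.
_BESA_1020_16 = {
    "Fp1": (-92, -72), "Fp2": (92, 72),
    "F7": (-92, -36), "F3": (-60, -51), "F4": (60, 51), "F8": (92, 36),
    "T3": (-92, 0), "C3": (-46, 0), "C4": (46, 0), "T4": (92, 0),
    "T5": (-92, 36), "P3": (-60, 51), "P4": (60, -51), "T6": (92, -36),
    "O1": (-92, 72), "O2": (92, -72),
}


@dataclass(frozen=True)
class HeadModel:
    """Concentric-shell spherical conductor (radii ascending, relative units)."""

    radii: tuple[float, ...] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, ...] = (1.0, 0.0125, 1.0)

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.conductivities):
            raise ValueError("need one conductivity per shell")
        if len(self.radii) < 1 or any(np.diff(self.radii) <= 0):
            raise ValueError("shell radii must be strictly increasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]


@dataclass
class SourceModel:
    """Lead field plus the geometry it was built from."""

    electrode_labels: list[str]
    electrode_positions: np.ndarray  # N_E x 3, on the outer shell
    source_grid: np.ndarray  # N_V x 3, inside the innermost shell
    lead_field: np.ndarray  # N_E x 3 N_V, average-referenced
    head_model: HeadModel
    parcellation: np.ndarray = field(default=None)  # N_V region labels

    def __post_init__(self) -> None:
        n_e, n_v = len(self.electrode_labels), self.source_grid.shape[0]
        if self.lead_field.shape != (n_e, 3 * n_v):
            raise ValueError("lead field must be N_E x 3 N_V")
        if self.parcellation is None:
            self.parcellation = np.zeros(n_v, dtype=int)
        self.parcellation = np.asarray(self.parcellation)
        if self.parcellation.shape[0] != n_v:
            raise ValueError("parcellation must label every source")

    @property
    def region_labels(self) -> np.ndarray:
        return np.unique(self.parcellation)

    @property
    def n_regions(self) -> int:
        return self.region_labels.size


def default_montage(head_model: HeadModel | None = None):
    """The 16-channel clinical 10-20 montage on the outer shell.

    Returns ``(labels, positions)`` with positions scaled to the scalp
    radius of ``head_model`` (unit sphere by default).
    """
    r = 1.0 if head_model is None else head_model.scalp_radius
    labels, positions = [], []
    for name, (theta, phi) in _BESA_1020_16.items():
        t, p = np.radians(theta), np.radians(phi)
        vec = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
        labels.append(name)
        positions.append(r * vec / np.linalg.norm(vec))
    return labels, np.asarray(positions)


def make_source_grid(
    n_sources: int = 200,
    head_model: HeadModel | None = None,
    max_relative_radius: float = 0.85,
    seed: int = 0,
) -> np.ndarray:
    """Random uniform source grid inside the innermost shell (seeded)."""
    hm = head_model or HeadModel()
    rng = np.random.default_rng(seed)
    r_max = max_relative_radius * hm.brain_radius
    pts = []
    while len(pts) < n_sources:
        cand = rng.uniform(-r_max, r_max, size=(2 * n_sources, 3))
        keep = np.linalg.norm(cand, axis=1) <= r_max
        pts.extend(cand[keep])
    return np.asarray(pts[:n_sources])


def make_parcellation(grid: np.ndarray, n_regions: int = 148, seed: int = 0) -> np.ndarray:
    """Partition the source grid into spatially compact regions (k-means).

    A generic, configurable parcellation standing in for an anatomical
    atlas; the default region count matches the 148-region (74 per
    hemisphere) scheme used downstream.
    """
    if n_regions > grid.shape[0]:
        raise ValueError("more regions than sources")
    km = KMeans(n_clusters=n_regions, n_init=4, random_state=seed)
    return km.fit_predict(grid)


def _radial_transfer(head_model: HeadModel, n_max: int) -> np.ndarray:
    """Scalp-surface radial factors t_n for a unit source term r^-(n+1).

    For each Legendre degree n the potential in shell k is
    ``A_k r^n + B_k r^-(n+1)`` (plus the source term in shell 1); the
    linear system encodes continuity of V and sigma dV/dr at each
    interface and zero current at the outer surface.
    """
    radii, sig = head_model.radii, head_model.conductivities
    n_shell = len(radii)
    r_out = radii[-1]
    t = np.zeros(n_max + 1)
    n_unk = 1 + 2 * (n_shell - 1)  # A1, then (A_k, B_k) for k >= 2
    for n in range(1, n_max + 1):
        a = np.zeros((n_unk, n_unk))
        rhs = np.zeros(n_unk)

        def col_a(k):  # index of A_k (k is 1-based shell index)
            return 0 if k == 1 else 1 + 2 * (k - 2)

        def col_b(k):
            return 2 + 2 * (k - 2)

        row = 0
        for k in range(1, n_shell):  # interface between shell k and k+1
            r = radii[k - 1]
            # potential continuity
            a[row, col_a(k)] += r**n
            if k > 1:
                a[row, col_b(k)] += r ** -(n + 1)
            a[row, col_a(k + 1)] -= r**n
            a[row, col_b(k + 1)] -= r ** -(n + 1)
            if k == 1:
                rhs[row] = -(r ** -(n + 1))  # source term lives in shell 1
            row += 1
            # radial current continuity
            a[row, col_a(k)] += sig[k - 1] * n * r ** (n - 1)
            if k > 1:
                a[row, col_b(k)] -= sig[k - 1] * (n + 1) * r ** -(n + 2)
            a[row, col_a(k + 1)] -= sig[k] * n * r ** (n - 1)
            a[row, col_b(k + 1)] += sig[k] * (n + 1) * r ** -(n + 2)
            if k == 1:
                rhs[row] = sig[0] * (n + 1) * r ** -(n + 2)
            row += 1
        # outer surface: zero radial current
        if n_shell == 1:
            a[row, col_a(1)] = n * r_out ** (n - 1)
            rhs[row] = (n + 1) * r_out ** -(n + 2)
        else:
            a[row, col_a(n_shell)] = n * r_out ** (n - 1)
            a[row, col_b(n_shell)] = -(n + 1) * r_out ** -(n + 2)
        sol = np.linalg.solve(a, rhs)
        if n_shell == 1:
            t[n] = sol[0] * r_out**n + r_out ** -(n + 1)
        else:
            t[n] = sol[col_a(n_shell)] * r_out**n + sol[col_b(n_shell)] * r_out ** -(n + 1)
    return t


def build_lead_field(
    montage=None,
    grid: np.ndarray | None = None,
    head_model: HeadModel | None = None,
    parcellation: np.ndarray | None = None,
    n_terms: int = 120,
) -> SourceModel:
    """Assemble the average-referenced lead field for a source grid.

    ``montage`` is ``(labels, positions)``; defaults to the 16-channel
    10-20 montage.  Columns come in (x, y, z) triplets per source.
    """
    hm = head_model or HeadModel()
    if montage is None:
        montage = default_montage(hm)
    labels, elec = montage
    elec = np.asarray(elec, dtype=float)
    if grid is None:
        grid = make_source_grid(head_model=hm)
    grid = np.asarray(grid, dtype=float)

    r_out = hm.scalp_radius
    if np.any(np.abs(np.linalg.norm(elec, axis=1) - r_out) > 1e-6 * r_out):
        raise ValueError("electrodes must lie on the outer shell surface")
    d = np.linalg.norm(elec[:, None] - elec[None, :], axis=-1)
    if np.any(d[np.triu_indices(len(elec), 1)] < 1e-9):
        raise ValueError("coincident electrode positions")
    b = np.linalg.norm(grid, axis=1)
    if np.any(b >= hm.brain_radius):
        raise ValueError("sources must lie strictly inside the innermost shell")

    n_e, n_v = elec.shape[0], grid.shape[0]
    t_n = _radial_transfer(hm, n_terms)
    sigma1 = hm.conductivities[0]

    e_hat = elec / r_out
    safe_b = np.where(b > 0, b, 1.0)
    q_hat = np.where(b[:, None] > 0, grid / safe_b[:, None], [0.0, 0.0, 1.0])
    cosg = np.clip(e_hat @ q_hat.T, -1.0, 1.0)  # N_E x N_V
    sing = np.sqrt(1.0 - cosg**2)
    # Unit tangent at the source pointing toward each electrode.
    t_vec = e_hat[:, None, :] - cosg[:, :, None] * q_hat[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_vec = np.where(sing[:, :, None] > 1e-12, t_vec / np.where(
            sing[:, :, None] > 1e-12, sing[:, :, None], 1.0), 0.0)

    # Accumulate the Legendre series for the radial and tangential parts.
    f_rad = np.zeros((n_e, n_v))
    f_tan = np.zeros((n_e, n_v))
    p_prev = np.ones_like(cosg)  # P_0
    p_cur = cosg.copy()  # P_1
    dp_prev = np.zeros_like(cosg)  # P_0'
    dp_cur = np.ones_like(cosg)  # P_1'
    b_pow = np.ones(n_v)  # b^(n-1)
    for n in range(1, len(t_n)):
        coef = (t_n[n] / (4.0 * np.pi * sigma1)) * b_pow  # per source
        f_rad += coef[None, :] * n * p_cur
        f_tan += coef[None, :] * sing * dp_cur
        # advance recurrences to degree n+1
        p_next = ((2 * n + 1) * cosg * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        b_pow = b_pow * b

    k = np.empty((n_e, 3 * n_v))
    for d_ax in range(3):
        k[:, d_ax::3] = f_rad * q_hat[None, :, d_ax] + f_tan * t_vec[:, :, d_ax]
    k -= k.mean(axis=0, keepdims=True)  # average-reference projection
    return SourceModel(
        electrode_labels=list(labels),
        electrode_positions=elec,
        source_grid=grid,
        lead_field=k,
        head_model=hm,
        parcellation=parcellation,
    )


def _centering(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def default_alpha(k: np.ndarray) -> float:
    """Regularization scale: 1e-6 x mean diagonal of K K^T."""
    return 1e-6 * float(np.mean(np.einsum("ij,ij->i", k, k)))


def minimum_norm_solve(phi: np.ndarray, k: np.ndarray, alpha: float) -> np.ndarray:
    """Reference-invariant regularized minimum-norm estimate J_hat."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if phi.shape[0] != k.shape[0]:
        if phi.shape[1] == k.shape[0]:  # a single potential vector
            phi = phi.T
        else:
            raise ValueError("phi row count must equal the electrode count")
    h = _centering(k.shape[0])
    m = k @ k.T + alpha * h
    return k.T @ np.linalg.pinv(m) @ (h @ phi)


def sloreta_standardize(j_hat: np.ndarray, k: np.ndarray, alpha: float) -> np.ndarray:
    """Standardized source power (N_V x T) from a minimum-norm estimate."""
    inv_blocks = _sloreta_blocks(k, alpha)
    n_v = k.shape[1] // 3
    j = j_hat.reshape(n_v, 3, -1)
    power = np.einsum("lit,lij,ljt->lt", j, inv_blocks, j)
    return np.clip(power, 0.0, None)


def _sloreta_blocks(k: np.ndarray, alpha: float) -> np.ndarray:
    """Inverses of the 3x3 diagonal blocks of K^T (K K^T + alpha H)^+ K."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    h = _centering(k.shape[0])
    minv = np.linalg.pinv(k @ k.T + alpha * h)
    n_v = k.shape[1] // 3
    blocks = np.empty((n_v, 3, 3))
    for l in range(n_v):
        kl = k[:, 3 * l : 3 * l + 3]
        s_ll = kl.T @ minv @ kl
        try:
            blocks[l] = np.linalg.inv(s_ll)
        except np.linalg.LinAlgError:
            logger.warning("singular variance block at source %d; using pseudoinverse", l)
            blocks[l] = np.linalg.pinv(s_ll)
    return blocks


class SLORETA(BaseEstimator, TransformerMixin):
    """sLORETA inverse operator as a fit/transform estimator.

    ``fit`` takes a :class:`SourceModel` (or a raw lead field) and
    precomputes the inverse operator; ``transform`` maps sensor data
    (N_E x T) to standardized source power (N_V x T).
    """

    def __init__(self, alpha: float | None = None):
        self.alpha = alpha

    def fit(self, source_model, y=None):
        k = source_model.lead_field if hasattr(source_model, "lead_field") else np.asarray(source_model)
        self.k_ = k
        self.alpha_ = default_alpha(k) if self.alpha is None else float(self.alpha)
        if self.alpha_ < 0:
            raise ValueError("alpha must be nonnegative")
        h = _centering(k.shape[0])
        self.t_ = k.T @ np.linalg.pinv(k @ k.T + self.alpha_ * h) @ h
        self.inv_blocks_ = _sloreta_blocks(k, self.alpha_)
        return self

    def current_density(self, phi: np.ndarray) -> np.ndarray:
        phi = np.atleast_2d(np.asarray(phi, dtype=float))
        if phi.shape[0] != self.k_.shape[0]:
            phi = phi.T
        return self.t_ @ phi

    def transform(self, phi: np.ndarray) -> np.ndarray:
        j = self.current_density(phi)
        n_v = self.k_.shape[1] // 3
        j = j.reshape(n_v, 3, -1)
        power = np.einsum("lit,lij,ljt->lt", j, self.inv_blocks_, j)
        return np.clip(power, 0.0, None)

    def localize(self, phi: np.ndarray) -> int:
        """Index of the source with maximal time-summed standardized power."""
        return int(np.argmax(self.transform(phi).sum(axis=1)))


def parcellate(source_ts: np.ndarray, parcellation: np.ndarray):
    """Average source time courses within regions.

    Returns ``(regions x T matrix, region labels)``; regions follow the
    sorted order of the unique labels.
    """
    parcellation = np.asarray(parcellation)
    source_ts = np.asarray(source_ts)
    if parcellation.shape[0] != source_ts.shape[0]:
        raise ValueError("parcellation must label every source row")
    labels = np.unique(parcellation)
    out = np.empty((labels.size, source_ts.shape[1]))
    for i, lab in enumerate(labels):
        members = parcellation == lab
        if not members.any():
            raise ValueError(f"region {lab} has no sources")
        out[i] = source_ts[members].mean(axis=0)
    return out, labels
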