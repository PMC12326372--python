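"""HYSCORE correlation-ridge and ELDOR-detected NMR prediction.

HYSCORE correlates the nuclear frequencies of the two electron manifolds:
each excited orientation contributes cross-peaks (nu_alpha, nu_beta).
Weak-coupling correlations appear in the (+,+) quadrant and cross the
anti-diagonal nu1 + nu2 = 2 nu_L at nu_L ± A_perp/2; strong-coupling
correlations appear in the (+,-) quadrant.  Peak intensities here are
heuristic — orientation excitation weight times an ESEEM-style
forbiddenness factor k = (nu_L * B_pseudo / (nu_alpha * nu_beta))^2
(capped at 1) that vanishes along hyperfine principal directions — so
ridge *positions* are quantitative while intensities are indicative only.

ELDOR-detected NMR is predicted as a stick spectrum at ± the nuclear
frequencies relative to the detection frequency, with the same
orientation x forbiddenness weighting (the experiment has zero response
when the field lies along a hyperfine principal axis, where the EPR
transitions are fully allowed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .fieldsweep import OrientationWeights, Spectrum1D, orientation_selection
from .nuclear_freq import manifold_frequencies_bulk
from .spin_system import SpinSystem, ValidationError, larmor_frequency_signed

__all__ = [
    "CorrelationPeakSet",
    "Map2D",
    "hyscore_peaks",
    "antidiagonal_crossings",
    "ridge_map",
    "eldor_stick_spectrum",
    "difference_spectrum",
]

#: default relative weight of correlations involving a double-quantum line
DQ_WEIGHT = 0.3


@dataclass
class CorrelationPeakSet:
    """Weighted HYSCORE cross-peaks with quadrant assignment.

    ``nu1``/``nu2`` are non-negative frequencies (MHz) of the alpha and
    beta manifold transitions, ``quadrant`` is +1 for (+,+) (weak
    coupling) and -1 for (+,-) (strong coupling), ``labels`` the
    transition-type pair, ``weight`` the orientation x allowedness
    weight, ``orientation`` the index into the orientation map.
    """

    nu1: np.ndarray
    nu2: np.ndarray
    quadrant: np.ndarray
    weight: np.ndarray
    labels: list[tuple[str, str]]
    orientation: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nu1 = np.asarray(self.nu1, dtype=float)
        self.nu2 = np.asarray(self.nu2, dtype=float)
        self.quadrant = np.asarray(self.quadrant, dtype=int)
        self.weight = np.asarray(self.weight, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=int)
        if np.any(self.nu1 < 0) or np.any(self.nu2 < 0):
            raise ValidationError("cross-peak frequencies must be non-negative")

    def __len__(self) -> int:
        return self.nu1.size

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (nu1, nu2) pairs."""
        return np.column_stack([self.nu1, self.nu2])

    def select(self, mask: np.ndarray) -> "CorrelationPeakSet":
        return CorrelationPeakSet(
            self.nu1[mask], self.nu2[mask], self.quadrant[mask], self.weight[mask],
            [lab for lab, m in zip(self.labels, mask) if m],
            self.orientation[mask], dict(self.meta),
        )


@dataclass
class Map2D:
    """Rasterized 2D frequency-frequency intensity map."""

    axis1: np.ndarray
    axis2: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, dtype=float)
        self.axis2 = np.asarray(self.axis2, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.axis1.size, self.axis2.size):
            raise ValidationError("intensity shape must be (len(axis1), len(axis2))")
        for ax in (self.axis1, self.axis2):
            if ax.size > 1 and np.any(np.diff(ax) <= 0):
                raise ValidationError("axes must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensities must be finite")


def _forbiddenness(a_matrix: np.ndarray, n_hat: np.ndarray, nu_l_signed: float,
                   nu_a: float, nu_b: float) -> float:
    """ESEEM-style modulation-depth factor, capped at 1.

    ``B_pseudo`` is the component of the hyperfine field n^T A that is
    perpendicular to the field direction (the pseudo-secular part); the
    factor vanishes when the field lies along a principal axis of A.
    """
    h_vec = n_hat @ a_matrix
    b_pseudo = np.linalg.norm(h_vec - (h_vec @ n_hat) * n_hat)
    denom = nu_a * nu_b
    if denom < 1e-12:
        return 0.0
    k = (abs(nu_l_signed) * b_pseudo / denom) ** 2
    return min(k, 1.0)


def hyscore_peaks(
    system: SpinSystem,
    nucleus_index: int,
    observer_field_mT: float,
    mw_freq_GHz: float = 34.3,
    bandwidth_MHz: float = 42.0,
    n_knots: int = 400,
    weight_cutoff: float = 0.01,
    orientations: OrientationWeights | None = None,
) -> CorrelationPeakSet:
    """Predict HYSCORE cross-peak positions for one nucleus.

    For every orientation whose excitation weight exceeds
    ``weight_cutoff``, all alpha-manifold frequencies are paired with all
    beta-manifold frequencies of the same nucleus (sq-sq and sq-dq for
    I=1).  The quadrant follows the coupling regime of the secular
    hyperfine component at that orientation.
    """
    entry = system.nuclei[nucleus_index]
    if orientations is None:
        orientations = orientation_selection(
            system, observer_field_mT, mw_freq_GHz, bandwidth_MHz, n_knots
        )
    nu_l_signed = larmor_frequency_signed(entry.nucleus, observer_field_mT)
    nu_l = abs(nu_l_signed)
    a = entry.hyperfine.matrix()

    # cutoff applies to the excitation factor so grid size does not matter
    active = np.nonzero(orientations.excitation > weight_cutoff)[0]
    dirs = orientations.directions[active]
    w_orient = orientations.combined[active]
    bulk = manifold_frequencies_bulk(system, nucleus_index, dirs, observer_field_mT)
    freqs_a, labs_a = bulk[0.5]
    freqs_b, labs_b = bulk[-0.5]

    # quadrant from the secular coupling regime at each orientation
    a_sec = np.einsum("ni,ij,nj->n", dirs, a, dirs)
    quad_per_orient = np.where(np.abs(a_sec) > 2.0 * nu_l, -1, 1)
    # forbiddenness ingredients, vectorised
    h_vec = dirs @ a
    b_pseudo = np.linalg.norm(h_vec - np.sum(h_vec * dirs, axis=1)[:, None] * dirs, axis=1)

    nu1_l, nu2_l, quad_l, wts_l, orient_l = [], [], [], [], []
    labels: list[tuple[str, str]] = []
    for ia, lab_a in enumerate(labs_a):
        for ib, lab_b in enumerate(labs_b):
            if lab_a == "dq" and lab_b == "dq":
                continue  # dq-dq correlations are not tracked
            f_a = freqs_a[:, ia]
            f_b = freqs_b[:, ib]
            k = (nu_l * b_pseudo / np.maximum(f_a * f_b, 1e-12)) ** 2
            np.minimum(k, 1.0, out=k)
            w = w_orient * k
            if lab_a == "dq" or lab_b == "dq":
                w = w * DQ_WEIGHT
            nu1_l.append(f_a)
            nu2_l.append(f_b)
            quad_l.append(quad_per_orient)
            wts_l.append(w)
            orient_l.append(active)
            labels.extend([(lab_a, lab_b)] * len(active))
    if nu1_l:
        nu1 = np.concatenate(nu1_l)
        nu2 = np.concatenate(nu2_l)
        quad = np.concatenate(quad_l)
        wts = np.concatenate(wts_l)
        orient = np.concatenate(orient_l)
    else:
        nu1 = nu2 = quad = wts = orient = np.empty(0)
    if nu1.size == 0:
        warnings.warn("no orientation exceeds the excitation-weight cutoff; empty peak set",
                      stacklevel=2)
    meta = {"B0_mT": observer_field_mT, "mw_freq_GHz": mw_freq_GHz,
            "bandwidth_MHz": bandwidth_MHz, "nucleus_index": nucleus_index,
            "nu_larmor_MHz": nu_l}
    return CorrelationPeakSet(
        nu1, nu2, quad.astype(int), wts, labels, orient.astype(int), meta,
    )


def antidiagonal_crossings(
    peaks: CorrelationPeakSet,
    nu_larmor: float,
    tolerance_MHz: float = 0.2,
    cluster_MHz: float = 0.4,
) -> list[tuple[float, float]]:
    """Ridge crossings of the anti-diagonal nu1 + nu2 = 2 nu_L.

    Returns ``(crossing_frequency, implied_A_perp)`` pairs: a (+,+)
    ridge point within ``tolerance_MHz`` perpendicular distance of the
    anti-diagonal crosses it at c = nu_L + (nu1 - nu2)/2, implying an
    in-plane coupling magnitude |A| = 2|c - nu_L|.

    To first order the whole weak-coupling ridge satisfies
    nu1 + nu2 = 2 nu_L, so for a rhombic in-plane tensor the crossing
    points form a continuum ending at the two canonical in-plane
    orientations; a contiguous run of crossings wider than
    ``cluster_MHz`` is therefore reported by its two extremes (the
    principal values), while a narrow run (axial tensor) collapses to
    its weighted mean.
    """
    if len(peaks) == 0:
        raise ValidationError("empty peak set")
    # the map is symmetric under nu1 <-> nu2: consider both orderings
    nu1 = np.concatenate([peaks.nu1, peaks.nu2])
    nu2 = np.concatenate([peaks.nu2, peaks.nu1])
    quad = np.concatenate([peaks.quadrant, peaks.quadrant])
    wts = np.concatenate([peaks.weight, peaks.weight])
    perp = np.abs(nu1 + nu2 - 2.0 * nu_larmor) / np.sqrt(2.0)
    mask = (perp <= tolerance_MHz) & (quad == 1)
    if not np.any(mask):
        return []
    c = nu_larmor + (nu1[mask] - nu2[mask]) / 2.0
    w = wts[mask]
    order = np.argsort(c)
    c, w = c[order], w[order]
    crossings: list[tuple[float, float]] = []
    start = 0
    for i in range(1, len(c) + 1):
        if i == len(c) or c[i] - c[i - 1] > cluster_MHz:
            cw = w[start:i]
            cc = c[start:i]
            if cc[-1] - cc[0] > cluster_MHz:
                # extended run: its ends are the canonical-orientation crossings
                for end in (cc[0], cc[-1]):
                    crossings.append((float(end), 2.0 * abs(end - nu_larmor)))
            else:
                center = float(np.average(cc, weights=cw)) if cw.sum() > 0 else float(cc.mean())
                crossings.append((center, 2.0 * abs(center - nu_larmor)))
            start = i
    return crossings


def ridge_map(
    peaks: CorrelationPeakSet,
    freq_range_MHz: tuple[float, float] = (0.0, 50.0),
    n_points: int = 256,
    splat_sigma_MHz: float = 0.3,
    symmetrize: bool = True,
) -> Map2D:
    """Rasterize a peak set onto a square frequency grid.

    Peaks are deposited bilinearly (total intensity equals the summed
    peak weights) and broadened with a 2D Gaussian; the map is
    symmetrized across the diagonal, matching the nu1 <-> nu2 exchange
    symmetry of the experiment.
    """
    lo, hi = freq_range_MHz
    axis = np.linspace(lo, hi, n_points)
    step = axis[1] - axis[0]
    if step > 1.0:
        warnings.warn(f"ridge-map grid is coarse ({step:.2f} MHz/pixel)", stacklevel=2)
    img = np.zeros((n_points, n_points))
    x = (peaks.nu1 - lo) / step
    y = (peaks.nu2 - lo) / step
    inside = (x >= 0) & (x <= n_points - 1) & (y >= 0) & (y <= n_points - 1)
    x, y, w = x[inside], y[inside], peaks.weight[inside]
    i0, j0 = np.floor(x).astype(int), np.floor(y).astype(int)
    fx, fy = x - i0, y - j0
    i1 = np.minimum(i0 + 1, n_points - 1)
    j1 = np.minimum(j0 + 1, n_points - 1)
    np.add.at(img, (i0, j0), w * (1 - fx) * (1 - fy))
    np.add.at(img, (i1, j0), w * fx * (1 - fy))
    np.add.at(img, (i0, j1), w * (1 - fx) * fy)
    np.add.at(img, (i1, j1), w * fx * fy)
    if splat_sigma_MHz > 0:
        img = gaussian_filter(img, splat_sigma_MHz / step, mode="constant")
    if symmetrize:
        img = 0.5 * (img + img.T)
    return Map2D(axis.copy(), axis.copy(), img, dict(peaks.meta))


def eldor_stick_spectrum(
    system: SpinSystem,
    nucleus_index: int,
    observer_field_mT: float,
    mw_freq_GHz: float = 34.3,
    bandwidth_MHz: float = 1.0,
    freq_range_MHz: tuple[float, float] = (-45.0, 45.0),
    n_points: int = 1801,
    broaden_MHz: float = 0.8,
    n_knots: int = 400,
    orientations: OrientationWeights | None = None,
) -> Spectrum1D:
    """ELDOR-detected NMR spectrum relative to the detection frequency.

    Sticks appear at ± each nuclear transition frequency, weighted by the
    orientation excitation weight times the forbiddenness factor, which
    is zero for the field along a hyperfine principal direction and for
    an uncoupled nucleus.
    """
    entry = system.nuclei[nucleus_index]
    if orientations is None:
        orientations = orientation_selection(
            system, observer_field_mT, mw_freq_GHz, bandwidth_MHz, n_knots
        )
    nu_l = abs(larmor_frequency_signed(entry.nucleus, observer_field_mT))
    a = entry.hyperfine.matrix()
    axis = np.linspace(*freq_range_MHz, n_points)
    step = axis[1] - axis[0]
    amp = np.zeros(n_points)
    active = np.nonzero(orientations.excitation > 1e-4)[0]
    dirs = orientations.directions[active]
    w_orient = orientations.combined[active]
    bulk = manifold_frequencies_bulk(system, nucleus_index, dirs, observer_field_mT)
    h_vec = dirs @ a
    b_pseudo = np.linalg.norm(h_vec - np.sum(h_vec * dirs, axis=1)[:, None] * dirs, axis=1)
    for ms in (0.5, -0.5):
        freqs, labs = bulk[ms]
        partner = np.mean(bulk[-ms][0], axis=1)  # partner-manifold mean, for k
        for it, lab in enumerate(labs):
            f = freqs[:, it]
            k = (nu_l * b_pseudo / np.maximum(f * partner, 1e-12)) ** 2
            np.minimum(k, 1.0, out=k)
            w = w_orient * k
            if lab == "dq":
                w = w * DQ_WEIGHT
            for sign in (1.0, -1.0):
                idx = (sign * f - axis[0]) / step
                ok = (idx >= 0) & (idx <= n_points - 1)
                i0 = np.floor(idx[ok]).astype(int)
                frac = idx[ok] - i0
                np.add.at(amp, i0, w[ok] * (1 - frac))
                i1 = i0 + 1
                inb = i1 < n_points
                np.add.at(amp, i1[inb], (w[ok] * frac)[inb])
    if broaden_MHz > 0:
        amp = gaussian_filter1d(amp, broaden_MHz / step, mode="constant")
    meta = {"B0_mT": observer_field_mT, "mw_freq_GHz": mw_freq_GHz,
            "bandwidth_MHz": bandwidth_MHz, "nucleus_index": nucleus_index}
    return Spectrum1D(axis, amp, "MHz", "stick", meta)


def difference_spectrum(a: Spectrum1D, b: Spectrum1D) -> Spectrum1D:
    """Pointwise a - b; axes must agree exactly."""
    if a.axis.shape != b.axis.shape or not np.allclose(a.axis, b.axis, rtol=0, atol=1e-12):
        raise ValidationError("spectra have mismatched axes")
    if a.axis_unit != b.axis_unit:
        raise ValidationError("spectra have different axis units")
    return Spectrum1D(a.axis.copy(), a.amplitude - b.amplitude, a.axis_unit, a.kind,
                      {"difference_of": (a.meta, b.meta)})
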