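"""Pseudo-AFM images, cosine-similarity scoring, the AFM flexible-fitting
restraint, and hinge-angle metrology on height images.

The restraint energy is V = kappa * kB * T * (1 - c.s.), where c.s. is the
cosine similarity between a reference height image and the pseudo-image
rendered from the current bead coordinates.  With the smooth (SOFTMAX)
renderer the energy is differentiable and the forces are analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import constants as C
from .forcefield import EnergyReport

__all__ = [
    "AFMImage", "TipModel", "TipSmoothing", "AFMRestraint",
    "render_pseudo_afm", "cosine_similarity", "afm_restraint_energy_forces",
    "measure_hinge_angle", "fit_angle_mixture", "MixtureFit",
    "write_afm_tsv", "read_afm_tsv",
]


@dataclass
class AFMImage:
    """Rectangular height grid (A) with a pixel size (A/pixel).

    ``heights[iy, ix]`` is the height above the stage of the pixel whose
    lower-left corner sits at ``origin + (ix, iy) * pixel_size`` in the
    simulation x-y plane.
    """

    heights: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    stage_height: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a nonempty 2-D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(self.heights < -1e-9):
            raise ValueError("heights must be >= 0 relative to the stage")
        self.heights = np.maximum(self.heights, 0.0)

    @property
    def shape(self):
        return self.heights.shape

    def pixel_centers(self):
        """(ny, nx) arrays of pixel-center x and y coordinates, A."""
        ny, nx = self.heights.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


class TipSmoothing(Enum):
    HARD_MAX = "hard_max"
    SOFTMAX = "softmax"


@dataclass
class TipModel:
    """Minimal tip: a lateral capture radius added to the pixel half-width.

    ``apex_radius = 0`` is a point tip (a bead contributes only to the pixel
    containing it).  Tip-sample mechanics are not modelled.
    """

    apex_radius: float = 0.0
    smoothing: TipSmoothing = TipSmoothing.SOFTMAX

    def __post_init__(self):
        if self.apex_radius < 0:
            raise ValueError("apex_radius must be >= 0")


@dataclass
class AFMRestraint:
    """Image restraint: strength kappa (in units of kB T), reference image,
    tip model and softmax sharpness beta (1/A)."""

    kappa: float
    reference: AFMImage
    tip: TipModel = field(default_factory=TipModel)
    beta: float = 2.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: lateral falloff stiffness of the smooth renderer, 1/A: a bead's smooth
#: contribution to a pixel decays over ~sqrt(h / LATERAL_STIFFNESS) beyond
#: the capture half-width, keeping the softmax close to the hard maximum
#: for beads more than ~2 A away from a pixel boundary.
LATERAL_STIFFNESS = 4.0


def _pixel_terms(positions, radii, image: AFMImage, tip: TipModel, beta):
    """Per-pixel, per-bead smooth contribution exponents
    s = beta*(h - LATERAL_STIFFNESS*(ex^2 + ey^2)) plus the lateral excess
    terms needed for gradients."""
    cx, cy = image.pixel_centers()
    cx = cx.ravel()[:, None]
    cy = cy.ravel()[:, None]
    x, y, z = positions[:, 0][None, :], positions[:, 1][None, :], \
        positions[:, 2][None, :]
    hw = image.pixel_size / 2.0 + tip.apex_radius
    h = z + radii[None, :]
    dx = x - cx
    dy = y - cy
    ex = np.maximum(np.abs(dx) - hw, 0.0)
    ey = np.maximum(np.abs(dy) - hw, 0.0)
    s = beta * (h - LATERAL_STIFFNESS * (ex ** 2 + ey ** 2))
    return s, dx, dy, ex, ey


def render_pseudo_afm(positions, radii, grid: AFMImage, tip: TipModel | None = None,
                      beta: float = 2.0) -> AFMImage:
    """Render a pseudo-AFM image from bead coordinates.

    Pixel height is the (soft) maximum over beads of the bead-top height
    ``z + r`` among beads whose lateral position falls within the pixel's
    capture half-width (``pixel_size/2 + apex_radius``, Chebyshev sense).
    ``grid`` supplies shape, pixel size and origin.  In SOFTMAX mode the
    height is a log-sum-exp that is smooth in the bead coordinates and
    converges to the hard maximum as ``beta`` grows; pixels with no bead
    render as 0 (the stage).
    """
    tip = tip or TipModel()
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    ny, nx = grid.heights.shape
    if positions.shape[0] == 0:
        return AFMImage(np.zeros((ny, nx)), grid.pixel_size, grid.origin)
    radii = np.asarray(radii, dtype=float)
    if tip.smoothing is TipSmoothing.HARD_MAX:
        cx, cy = grid.pixel_centers()
        hw = grid.pixel_size / 2.0 + tip.apex_radius
        h = positions[:, 2] + radii
        heights = np.zeros((ny, nx))
        inside_x = np.abs(positions[:, 0][None, None, :] - cx[..., None]) <= hw
        inside_y = np.abs(positions[:, 1][None, None, :] - cy[..., None]) <= hw
        captured = inside_x & inside_y
        contrib = np.where(captured, h[None, None, :], -np.inf)
        heights = np.max(contrib, axis=2)
        heights = np.maximum(heights, 0.0)
    else:
        s, *_ = _pixel_terms(positions, radii, grid, tip, beta)
        m = np.maximum(s.max(axis=1), 0.0)
        logd = m + np.log(np.exp(-m) + np.exp(s - m[:, None]).sum(axis=1))
        heights = (logd / beta).reshape(ny, nx)
    return AFMImage(heights, grid.pixel_size, grid.origin)


def cosine_similarity(image_a: AFMImage, image_b: AFMImage) -> float:
    """Cosine similarity sum(Ha*Hb) / (||Ha|| ||Hb||), in [0, 1].

    Symmetric and invariant under rescaling either image; undefined (raises)
    if either image is identically zero.
    """
    a = image_a.heights.ravel()
    b = image_b.heights.ravel()
    if a.shape != b.shape:
        raise ValueError("images must share the same grid shape")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for an all-zero image")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# restraint energy / forces
# ---------------------------------------------------------------------------

def afm_restraint_energy_forces(positions, radii, restraint: AFMRestraint,
                                temperature=C.DEFAULT_TEMPERATURE) -> EnergyReport:
    """V = kappa kB T (1 - c.s.) with analytic forces via the chain rule
    through the smooth pixel heights.

    If the rendered pseudo-image is all zero (the molecule left the imaged
    region) the similarity is undefined: no force is applied and the frame
    is flagged.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    kT = C.KB_KCAL * temperature
    report = EnergyReport(forces=np.zeros_like(positions))
    ref = restraint.reference
    beta = restraint.beta

    s, dx, dy, ex, ey = _pixel_terms(positions, radii, ref, restraint.tip, beta)
    m = np.maximum(s.max(axis=1), 0.0)
    E = np.exp(s - m[:, None])                      # (P, N), shifted
    D = np.exp(-m) + E.sum(axis=1)                  # shifted denominator
    H = ((m + np.log(D)) / beta)                    # (P,) pixel heights

    href = ref.heights.ravel()
    nh = np.linalg.norm(H)
    nr = np.linalg.norm(href)
    if nr == 0.0:
        raise ValueError("reference image is all zero")
    if nh < 1e-12:
        report.terms["afm_restraint"] = restraint.kappa * kT
        report.flags.append("pseudo-image all zero: no restraint force")
        return report

    dot = float(href @ H)
    cs = dot / (nh * nr)
    energy = restraint.kappa * kT * (1.0 - cs)
    # d cs / d H_p
    g = href / (nh * nr) - dot * H / (nh ** 3 * nr)
    # d H_p / d bead coordinates through the shifted softmax
    W = (g / D)[:, None] * E / beta                 # (P, N)
    sgn_x = np.sign(dx) * (ex > 0.0)
    sgn_y = np.sign(dy) * (ey > 0.0)
    lat = 2.0 * beta * LATERAL_STIFFNESS
    dcs_dx = np.sum(W * (-lat * ex * sgn_x), axis=0)
    dcs_dy = np.sum(W * (-lat * ey * sgn_y), axis=0)
    dcs_dz = np.sum(W * beta, axis=0)
    # F = -dV/dr = kappa kB T * d cs / d r
    pref = restraint.kappa * kT
    report.forces[:, 0] = pref * dcs_dx
    report.forces[:, 1] = pref * dcs_dy
    report.forces[:, 2] = pref * dcs_dz
    report.terms["afm_restraint"] = energy
    return report


# ---------------------------------------------------------------------------
# hinge-angle metrology
# ---------------------------------------------------------------------------

def measure_hinge_angle(image: AFMImage, globular_domain_mask=None,
                        arm_length_px: int = 10, arm_width_px: int = 5,
                        inner_offset_px: float = 4.0,
                        min_separation_deg: float = 20.0,
                        return_directions: bool = False):
    """Hinge angle from a height image, in degrees within [0, 180].

    From the highest pixel inside the mask, height sums are accumulated in
    rectangular regions ``arm_length_px`` long and ``arm_width_px`` wide
    extending radially on a 1-degree angular grid (bilinear sampling); the
    two best local maxima of this angular profile (at least
    ``min_separation_deg`` apart) define the arm directions, and the angle
    between them is returned.  The window starts ``inner_offset_px`` out
    from the peak so that near-junction pixels of the opposite arm do not
    bias the directions inward.
    """
    h = image.heights
    mask = np.ones_like(h, dtype=bool) if globular_domain_mask is None \
        else np.asarray(globular_domain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty globular-domain mask")
    masked = np.where(mask, h, -np.inf)
    cy, cx = np.unravel_index(np.argmax(masked), h.shape)

    ny, nx = h.shape
    profile = np.zeros(360)
    half_w = (arm_width_px - 1) / 2.0
    t_steps = np.arange(inner_offset_px, inner_offset_px + arm_length_px,
                        dtype=float)
    w_steps = np.arange(-half_w, half_w + 0.5)
    for k, a in enumerate(np.deg2rad(np.arange(360))):
        ux, uy = np.cos(a), np.sin(a)
        px = (cx + t_steps[:, None] * ux + w_steps[None, :] * (-uy)).ravel()
        py = (cy + t_steps[:, None] * uy + w_steps[None, :] * ux).ravel()
        x0 = np.floor(px).astype(int)
        y0 = np.floor(py).astype(int)
        fx, fy = px - x0, py - y0
        ok = (x0 >= 0) & (x0 < nx - 1) & (y0 >= 0) & (y0 < ny - 1)
        x0, y0, fx, fy = x0[ok], y0[ok], fx[ok], fy[ok]
        profile[k] = np.sum(
            h[y0, x0] * (1 - fx) * (1 - fy) + h[y0, x0 + 1] * fx * (1 - fy)
            + h[y0 + 1, x0] * (1 - fx) * fy + h[y0 + 1, x0 + 1] * fx * fy)

    # arms must carry appreciable height out to the window radii; a single
    # compact spot leaves only edge ripple in the profile
    pmin, pmax = profile.min(), profile.max()
    peak_height = float(h[cy, cx])
    if pmax < 0.1 * arm_length_px * peak_height:
        raise ValueError("arms not resolved: no significant radial ridges")
    # circular local maxima above the half-range level
    left = np.roll(profile, 1)
    right = np.roll(profile, -1)
    peaks = np.flatnonzero((profile > left) & (profile >= right)
                           & (profile >= pmin + 0.5 * (pmax - pmin)))
    if peaks.size < 2:
        raise ValueError("arms not resolved: fewer than two angular maxima")
    order = peaks[np.argsort(profile[peaks])[::-1]]
    chosen: list[int] = []
    for p in order:
        if all(_circ_sep(p, q) >= min_separation_deg for q in chosen):
            chosen.append(int(p))
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise ValueError("arms not resolved: maxima too close together")
    sep = _circ_sep(chosen[0], chosen[1])
    angle = min(sep, 360.0 - sep) if sep > 180.0 else sep
    if return_directions:
        return float(angle), tuple(chosen)
    return float(angle)


def _circ_sep(a, b):
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


# ---------------------------------------------------------------------------
# angle-distribution mixture fit
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    converged: bool
    flags: list = field(default_factory=list)


def fit_angle_mixture(angles, n_components: int = 2, seed: int = 0) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture of an angle sample (degrees).

    EM with k-means initialization (scikit-learn), deterministic for a
    given seed.  Components are returned sorted by mean.  A degenerate
    component (vanishing spread) triggers one re-initialization and a flag.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(angles, dtype=float).reshape(-1, 1)
    if x.shape[0] < 10 * n_components:
        raise ValueError("need at least 10 samples per mixture component")
    flags = []
    if np.ptp(x) < 1e-9:
        flags.append("degenerate: all angles identical")
        return MixtureFit(weights=np.array([1.0] * n_components) / n_components,
                          means=np.full(n_components, float(x[0, 0])),
                          sds=np.zeros(n_components), converged=False,
                          flags=flags)
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         n_init=3, random_state=seed, reg_covar=1e-6)
    gm.fit(x)
    sds = np.sqrt(gm.covariances_.reshape(-1))
    if np.any(sds < 1e-3):
        flags.append("degenerate component: re-initialized")
        gm = GaussianMixture(n_components=n_components, covariance_type="full",
                             n_init=5, random_state=seed + 1, reg_covar=1e-4)
        gm.fit(x)
        sds = np.sqrt(gm.covariances_.reshape(-1))
    order = np.argsort(gm.means_.reshape(-1))
    return MixtureFit(weights=gm.weights_[order],
                      means=gm.means_.reshape(-1)[order],
                      sds=sds[order], converged=bool(gm.converged_),
                      flags=flags)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_afm_tsv(image: AFMImage, path) -> None:
    """Write a height grid as TSV with a one-line parameter header."""
    with open(path, "w") as fh:
        fh.write(f"# pixel_size={image.pixel_size:.6g}\t"
                 f"origin_x={image.origin[0]:.6g}\t"
                 f"origin_y={image.origin[1]:.6g}\n")
        np.savetxt(fh, image.heights, fmt="%.6f", delimiter="\t")


def read_afm_tsv(path) -> AFMImage:
    with open(path) as fh:
        header = fh.readline()
        fields = dict(tok.split("=") for tok in header.lstrip("# ").split())
        heights = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return AFMImage(heights, float(fields["pixel_size"]),
                    (float(fields.get("origin_x", 0.0)),
                     float(fields.get("origin_y", 0.0))))
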