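"""Synthetic cine DENSE phantom with analytic ground-truth motion and strain.

The phantom is a contracting, twisting annulus (a mid-ventricular short-axis
left-ventricle stand-in). A material point at reference polar coordinates
(R, Theta) moves to

    r(R, t)     = R * (1 - c(t) * w(R)),
    theta(R, t) = Theta + tau(t),

where c(t) is a smooth systole/diastole time course peaking at
``peak_contraction_fraction``, w(R) a transmural weighting (1 at the
endocardium, linear falloff ``transmural_falloff`` toward the epicardium) and
tau(t) the twist. Because the twist is independent of R, the Green-Lagrange
circumferential strain has the closed form

    E_cc = ((r/R)^2 - 1) / 2,

which the package uses as the strain oracle for the whole analysis chain.

DENSE signal model per encoding e in {reference, x, y} and phase cycle
p in {0, 1}:

    I_c(x) = S_c(x) * [ A_ste(x, t) * exp(i (2 pi ke u_e(x) + p*pi + phi_bg(x)))
                        + A_art(x)  * exp(i phi_bg(x)) ],

so the stimulated echo flips sign between the two phase cycles while the
artifact (T1-recovery) echo is cycle-invariant; the complex difference of the
two cycles divided by two cancels the artifact exactly and the ratio to the
reference encoding removes the static background phase phi_bg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class PhantomConfig:
    """Geometry, motion and signal parameters of the numerical phantom."""

    grid_size: int = 128
    fov_mm: float = 156.0
    n_phases: int = 20
    n_coils: int = 24
    n_phase_cycles: int = 2
    n_encodings: int = 3
    epicardial_radius_mm: float = 32.0
    endocardial_radius_mm: float = 20.0
    peak_contraction_fraction: float = 0.15
    peak_twist_deg: float = 5.0
    systole_fraction: float = 0.35
    end_diastolic_residual: float = 0.3
    bulk_translation_mm: tuple = (1.5, 0.8)
    transmural_falloff: float = 0.0
    ke_cyc_per_mm: float = 0.10
    kd_cyc_per_mm: float = 0.08  # through-plane dephasing; metadata only
    ste_amplitude: float = 1.0
    artifact_amplitude: float = 0.3
    t1_decay_per_phase: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0 < self.endocardial_radius_mm < self.epicardial_radius_mm < self.fov_mm / 2
        ):
            raise ValueError("need endo < epi < fov/2")
        if not 0 <= self.peak_contraction_fraction < 1:
            raise ValueError("peak_contraction_fraction must be in [0, 1)")
        if self.n_encodings < 3:
            raise ValueError("need at least 3 encodings (reference, x, y)")
        if self.n_phase_cycles not in (1, 2):
            raise ValueError("n_phase_cycles must be 1 or 2")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.grid_size

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center positions in mm, centered at the FOV center."""
        pos = (np.arange(self.grid_size) - self.grid_size / 2) * self.pixel_mm
        return np.meshgrid(pos, pos, indexing="ij")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Analytic reference the acceptance checks measure against."""

    config: PhantomConfig
    displacement_mm: np.ndarray  # (Nph, Nx, Ny, 2), Lagrangian, reference grid
    eulerian_displacement_mm: np.ndarray  # (Nph, Nx, Ny, 2), at current pixels
    ecc_map: np.ndarray  # (Nph, Nx, Ny), on the deformed grid
    myocardial_mask: np.ndarray  # (Nph, Nx, Ny) bool, deformed annulus
    reference_images: np.ndarray = field(default=None)  # (Nx,Ny,Nch,Nph,Npc,Nenc)


# ---------------------------------------------------------------------------
# motion model
# ---------------------------------------------------------------------------

def _course_shape(config: PhantomConfig, frame: int) -> float:
    """Unit-peak systole/diastole time course: 0 at frame 0, 1 at systole."""
    if not 0 <= frame < config.n_phases:
        raise ValueError(f"frame {frame} out of range [0, {config.n_phases})")
    if config.n_phases == 1:
        return 0.0
    t = frame / (config.n_phases - 1)
    ts = config.systole_fraction
    if t <= ts:
        shape = np.sin(0.5 * np.pi * t / ts) ** 2
    else:
        # relaxation toward a residual deformation: cines typically end
        # before full return to the end-diastolic state
        r = config.end_diastolic_residual
        shape = r + (1 - r) * np.cos(0.5 * np.pi * (t - ts) / (1 - ts)) ** 2
    return float(shape)


def contraction_course(config: PhantomConfig, frame: int) -> float:
    """c(t): mid-wall radial shrink fraction at the given frame."""
    return config.peak_contraction_fraction * _course_shape(config, frame)


def twist_rad(config: PhantomConfig, frame: int) -> float:
    """tau(t): twist angle sharing the contraction time course."""
    return np.deg2rad(config.peak_twist_deg) * _course_shape(config, frame)


def transmural_weight(config: PhantomConfig, radius_mm: np.ndarray) -> np.ndarray:
    """w(R): 1 at the endocardium, falling off linearly toward the epicardium."""
    frac = np.clip(
        (radius_mm - config.endocardial_radius_mm)
        / (config.epicardial_radius_mm - config.endocardial_radius_mm),
        0.0,
        1.0,
    )
    return 1.0 - config.transmural_falloff * frac


def bulk_translation(config: PhantomConfig, frame: int) -> np.ndarray:
    """Rigid in-plane translation b(t) (mm), sharing the contraction course.

    Emulates the net cardiac translation through the cycle; being rigid it
    contributes displacement (and hence encoded phase) but zero strain.
    """
    shape = _course_shape(config, frame)
    return np.asarray(config.bulk_translation_mm, dtype=float) * shape


def deform_points(
    config: PhantomConfig, frame: int, ref_xy_mm: np.ndarray
) -> np.ndarray:
    """Lagrangian map: reference positions (..., 2) -> deformed positions (mm)."""
    c = contraction_course(config, frame)
    tau = twist_rad(config, frame)
    x, y = ref_xy_mm[..., 0], ref_xy_mm[..., 1]
    radius = np.hypot(x, y)
    theta = np.arctan2(y, x)
    r_new = radius * (1.0 - c * transmural_weight(config, radius))
    th_new = theta + tau
    out = np.stack([r_new * np.cos(th_new), r_new * np.sin(th_new)], axis=-1)
    return out + bulk_translation(config, frame)


def _radius_inverse(config: PhantomConfig, frame: int):
    """Monotone inverse of R -> r(R, t), tabulated on a fine radial grid."""
    c = contraction_course(config, frame)
    r_ref = np.linspace(0.0, config.fov_mm, 4096)
    r_def = r_ref * (1.0 - c * transmural_weight(config, r_ref))
    return lambda r: np.interp(r, r_def, r_ref)


def make_motion_field(
    config: PhantomConfig, frame: int
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement field (mm, 2-vector) on the reference grid + deformed mask.

    The displacement is Lagrangian: ``u(X) = phi(X, t) - X`` evaluated at
    pixel-center reference positions X. The mask marks pixels inside the
    deformed annulus at the current frame.
    """
    xx, yy = config.pixel_coords()
    ref = np.stack([xx, yy], axis=-1)
    disp = deform_points(config, frame, ref) - ref
    mask = deformed_mask(config, frame)
    return disp, mask


def deformed_mask(config: PhantomConfig, frame: int) -> np.ndarray:
    """Boolean annulus mask in the current (deformed) configuration."""
    c = contraction_course(config, frame)
    r_endo = config.endocardial_radius_mm * (
        1.0 - c * float(transmural_weight(config, np.array(config.endocardial_radius_mm)))
    )
    r_epi = config.epicardial_radius_mm * (
        1.0 - c * float(transmural_weight(config, np.array(config.epicardial_radius_mm)))
    )
    xx, yy = config.pixel_coords()
    b = bulk_translation(config, frame)
    radius = np.hypot(xx - b[0], yy - b[1])
    return (radius >= r_endo) & (radius <= r_epi)


def eulerian_displacement(config: PhantomConfig, frame: int) -> np.ndarray:
    """Displacement of the tissue currently at each pixel: u(x) = x - X(x)."""
    xx, yy = config.pixel_coords()
    b = bulk_translation(config, frame)
    radius = np.hypot(xx - b[0], yy - b[1])
    theta = np.arctan2(yy - b[1], xx - b[0])
    inv = _radius_inverse(config, frame)
    r_ref = inv(radius)
    th_ref = theta - twist_rad(config, frame)
    ref_x = r_ref * np.cos(th_ref)
    ref_y = r_ref * np.sin(th_ref)
    return np.stack([xx - ref_x, yy - ref_y], axis=-1)


def analytic_ecc(config: PhantomConfig, frame: int) -> np.ndarray:
    """Green-Lagrange circumferential strain on the deformed grid.

    For the radial-scaling-plus-uniform-twist map the circumferential stretch
    is r/R, hence E_cc = ((r/R)^2 - 1)/2; rigid motion gives exactly zero.
    """
    xx, yy = config.pixel_coords()
    b = bulk_translation(config, frame)
    radius = np.hypot(xx - b[0], yy - b[1])
    inv = _radius_inverse(config, frame)
    r_ref = inv(radius)
    with np.errstate(divide="ignore", invalid="ignore"):
        stretch = np.where(r_ref > 0, radius / np.maximum(r_ref, 1e-12), 1.0)
    return 0.5 * (stretch**2 - 1.0)


# ---------------------------------------------------------------------------
# signal rendering
# ---------------------------------------------------------------------------

def _background_phase(config: PhantomConfig) -> np.ndarray:
    xx, yy = config.pixel_coords()
    half = config.fov_mm / 2
    return 0.8 * np.pi * (xx / half) + 0.5 * np.pi * (yy / half)


def _artifact_image(config: PhantomConfig) -> np.ndarray:
    xx, yy = config.pixel_coords()
    sigma = 0.35 * config.fov_mm
    return config.artifact_amplitude * np.exp(-(xx**2 + yy**2) / (2 * sigma**2))


def _soft_annulus(config: PhantomConfig, frame: int) -> np.ndarray:
    """Annulus amplitude with a ~1-pixel smoothed edge (limits Gibbs ringing)."""
    c = contraction_course(config, frame)
    w_endo = float(transmural_weight(config, np.array(config.endocardial_radius_mm)))
    w_epi = float(transmural_weight(config, np.array(config.epicardial_radius_mm)))
    r_endo = config.endocardial_radius_mm * (1.0 - c * w_endo)
    r_epi = config.epicardial_radius_mm * (1.0 - c * w_epi)
    xx, yy = config.pixel_coords()
    b = bulk_translation(config, frame)
    radius = np.hypot(xx - b[0], yy - b[1])
    edge = config.pixel_mm
    inner = 0.5 * (1 + np.tanh((radius - r_endo) / (0.5 * edge)))
    outer = 0.5 * (1 + np.tanh((r_epi - radius) / (0.5 * edge)))
    return inner * outer


def render_dense_images(
    config: PhantomConfig, coil_sensitivities: np.ndarray | None = None
) -> GroundTruth:
    """Render noise-free 6D DENSE images + analytic ground truth.

    Parameters
    ----------
    coil_sensitivities : (Nx, Ny, Nch) complex array or None
        None renders single-"coil" images with unit sensitivity repeated to
        ``n_coils`` channels is *not* done; instead Nch=1 flat sensitivity.
    """
    n = config.grid_size
    if coil_sensitivities is None:
        coil_sensitivities = np.ones((n, n, 1), dtype=complex)
    if coil_sensitivities.shape[:2] != (n, n):
        raise ValueError("coil map grid does not match phantom grid")
    nch = coil_sensitivities.shape[2]
    nph, npc, nenc = config.n_phases, config.n_phase_cycles, config.n_encodings

    phi_bg = _background_phase(config)
    art = _artifact_image(config) * np.exp(1j * phi_bg)

    images = np.zeros((n, n, nch, nph, npc, nenc), dtype=complex)
    disp_ref = np.zeros((nph, n, n, 2))
    disp_eul = np.zeros((nph, n, n, 2))
    ecc = np.zeros((nph, n, n))
    masks = np.zeros((nph, n, n), dtype=bool)

    for f in range(nph):
        disp_ref[f], masks[f] = make_motion_field(config, f)
        u = eulerian_displacement(config, f)
        disp_eul[f] = u
        ecc[f] = analytic_ecc(config, f)
        amp = (
            config.ste_amplitude
            * np.exp(-config.t1_decay_per_phase * f)
            * _soft_annulus(config, f)
        )
        for e in range(nenc):
            if e == 0:
                phi_enc = np.zeros((n, n))
            elif e == 1:
                phi_enc = 2 * np.pi * config.ke_cyc_per_mm * u[..., 0]
            else:
                phi_enc = 2 * np.pi * config.ke_cyc_per_mm * u[..., 1]
            for p in range(npc):
                ste = amp * np.exp(1j * (phi_enc + p * np.pi + phi_bg))
                images[:, :, :, f, p, e] = (
                    coil_sensitivities * (ste + art)[..., None]
                )

    return GroundTruth(
        config=config,
        displacement_mm=disp_ref,
        eulerian_displacement_mm=disp_eul,
        ecc_map=ecc,
        myocardial_mask=masks,
        reference_images=images,
    )
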