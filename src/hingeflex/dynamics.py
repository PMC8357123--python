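"""Langevin dynamics and simulation protocols.

The integrator is an underdamped splitting scheme with an exact
Ornstein-Uhlenbeck friction/noise substep (BAOAB ordering): it satisfies
fluctuation-dissipation for any friction and reduces to velocity Verlet as
the friction vanishes.  Time, friction and masses are dimensionless CG
units; all rates downstream are reported per integration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import constants as C
from .forcefield import ElectrostaticParams, EnergyModel
from .system import CGSystem, Trajectory, merge_systems

__all__ = ["LangevinParams", "SimulationConfig", "langevin_step",
           "run_simulation", "place_random_dna",
           "release_restraint_protocol", "initial_velocities"]


@dataclass
class LangevinParams:
    friction: float = C.DEFAULT_FRICTION      # 1 / CG time
    timestep: float = C.DEFAULT_TIMESTEP      # CG time
    temperature: float = C.DEFAULT_TEMPERATURE  # K
    mass: float | np.ndarray = C.DEFAULT_MASS   # CG mass units

    def __post_init__(self):
        if self.friction <= 0 or self.timestep <= 0:
            raise ValueError("friction and timestep must be positive")
        if self.timestep * self.friction >= 2.0:
            raise ValueError("unstable setting: timestep * friction must be < 2")


@dataclass
class SimulationConfig:
    """Run settings: length, thermodynamic state, restraint, and seed."""

    n_steps: int = 10000
    save_interval: int = 100
    seed: int = 0
    temperature: float = C.DEFAULT_TEMPERATURE
    friction: float = C.DEFAULT_FRICTION
    timestep: float = C.DEFAULT_TIMESTEP
    mass: float = C.DEFAULT_MASS
    box: tuple | None = None                  # A, periodic wrap for pairs
    salt: float | None = None                 # mol/L; None disables DH
    dielectric: float = C.DEFAULT_DIELECTRIC
    kappa: float = 0.0                        # AFM restraint strength, kB T
    reference_image: object = None            # AFMImage, set when kappa > 0
    beta: float = 2.0                         # softmax sharpness, 1/A
    apex_radius: float = 0.0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def langevin(self) -> LangevinParams:
        return LangevinParams(self.friction, self.timestep,
                              self.temperature, self.mass)

    def snapshot(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "reference_image"}
        d["has_reference_image"] = self.reference_image is not None
        if d.get("box") is not None:
            d["box"] = [float(x) for x in np.asarray(d["box"]).ravel()]
        return d

    def to_yaml(self, path) -> None:
        """Write the run settings (minus the image) as a YAML file; the
        reference image travels separately as a TSV grid."""
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.snapshot(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, reference_image=None) -> "SimulationConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data.pop("has_reference_image", None)
        if data.get("box") is not None:
            data["box"] = tuple(data["box"])
        return cls(reference_image=reference_image, **data)


def initial_velocities(n, params: LangevinParams, rng) -> np.ndarray:
    """Maxwell-Boltzmann velocity draw."""
    kT = C.KB_KCAL * params.temperature
    sigma = np.sqrt(kT / np.asarray(params.mass))
    return rng.normal(size=(n, 3)) * np.atleast_1d(sigma)[:, None] \
        if np.ndim(params.mass) else rng.normal(scale=sigma, size=(n, 3))


def langevin_step(positions, velocities, forces, force_fn,
                  params: LangevinParams, rng):
    """One BAOAB update.  ``forces`` must be current for ``positions``;
    returns (positions, velocities, forces) with forces recomputed at the
    new positions.  Deterministic given the rng stream."""
    dt = params.timestep
    m = params.mass
    kT = C.KB_KCAL * params.temperature
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt(kT / m * (1.0 - c1 * c1))

    velocities = velocities + (0.5 * dt / m) * forces
    positions = positions + 0.5 * dt * velocities
    if params.temperature > 0:
        velocities = c1 * velocities + c2 * rng.standard_normal(
            size=velocities.shape)
    else:
        velocities = c1 * velocities
    positions = positions + 0.5 * dt * velocities
    forces = force_fn(positions)
    velocities = velocities + (0.5 * dt / m) * forces
    return positions, velocities, forces


def _build_model(system: CGSystem, config: SimulationConfig,
                 kappa_override=None) -> EnergyModel:
    from .afm import AFMRestraint, TipModel

    electro = None
    if config.salt is not None:
        electro = ElectrostaticParams(ionic_strength=config.salt,
                                      temperature=config.temperature,
                                      dielectric=config.dielectric)
    kappa = config.kappa if kappa_override is None else kappa_override
    restraint = None
    if kappa > 0 and config.reference_image is not None:
        restraint = AFMRestraint(kappa=kappa, reference=config.reference_image,
                                 tip=TipModel(apex_radius=config.apex_radius),
                                 beta=config.beta)
    sys_run = system
    if config.box is not None:
        sys_run = system.copy()
        sys_run.box = np.asarray(config.box, dtype=float)
    return EnergyModel(sys_run, electrostatics=electro, restraint=restraint,
                       temperature=config.temperature)


def run_simulation(cg_system: CGSystem, config: SimulationConfig,
                   model: EnergyModel | None = None,
                   initial_positions=None) -> Trajectory:
    """Integrate and save frames every ``save_interval`` steps.

    Pair interactions use minimum-image wrapping when a box is set, while
    stored coordinates stay unwrapped.  The trajectory records the seed, a
    config snapshot, and per-term energies (plus the restraint similarity
    ``afm_cs`` when restrained) at each saved frame.
    """
    if model is None:
        model = _build_model(cg_system, config)
    params = config.langevin()
    rng = np.random.default_rng(config.seed)
    pos = np.array(cg_system.positions if initial_positions is None
                   else initial_positions, dtype=float)
    vel = initial_velocities(pos.shape[0], params, rng)

    def force_fn(x):
        return model.energy_forces(x).forces

    report = model.energy_forces(pos)
    forces = report.forces
    kT = C.KB_KCAL * config.temperature

    steps, frames = [0], [pos.copy()]
    logs: dict[str, list] = {name: [val] for name, val in report.terms.items()}
    if model.restraint is not None:
        logs["afm_cs"] = [1.0 - report.terms["afm_restraint"]
                          / (model.restraint.kappa * kT)]
    for step in range(1, config.n_steps + 1):
        pos, vel, forces = langevin_step(pos, vel, forces, force_fn,
                                         params, rng)
        if step % config.save_interval == 0 or step == config.n_steps:
            if not np.all(np.isfinite(pos)):
                fmax = float(np.nanmax(np.abs(forces)))
                raise FloatingPointError(
                    f"non-finite positions at step {step}; "
                    f"largest force component {fmax:.3g}")
            if steps[-1] == step:
                continue
            steps.append(step)
            frames.append(pos.copy())
            report = model.energy_forces(pos)
            for name, val in report.terms.items():
                logs.setdefault(name, []).append(val)
            if model.restraint is not None:
                logs["afm_cs"].append(
                    1.0 - report.terms["afm_restraint"]
                    / (model.restraint.kappa * kT))

    traj = Trajectory(steps=np.array(steps), positions=np.array(frames),
                      seed=config.seed, config=config.snapshot(),
                      logs={k: np.asarray(v) for k, v in logs.items()})
    return traj


# ---------------------------------------------------------------------------
# DNA placement
# ---------------------------------------------------------------------------

def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (random unit quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def place_random_dna(cg_system: CGSystem, duplex: CGSystem, n_copies: int = 5,
                     min_separation: float = 20.0, seed=None,
                     box=None, max_retries: int = 500) -> CGSystem:
    """Add ``n_copies`` randomly placed/oriented duplex copies to a system.

    Copy centroids are uniform in the box and orientations uniform on
    SO(3); a placement is rejected unless every inter-molecule bead-bead
    distance (to the existing system and to earlier copies) is at least
    ``min_separation``.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box if box is not None else cg_system.box, dtype=float)
    if box is None or box.size != 3:
        raise ValueError("a 3-edge box is required for placement")
    merged = cg_system.copy()
    merged.box = box
    obstacles = [cg_system.positions] if cg_system.n_beads else []
    centered = duplex.positions - duplex.positions.mean(axis=0)
    for k in range(n_copies):
        placed = None
        for _ in range(max_retries):
            R = _random_rotation(rng)
            t = rng.uniform(0.0, box)
            cand = centered @ R.T + t
            ok = True
            for obs in obstacles:
                d2 = np.sum((obs[:, None, :] - cand[None, :, :]) ** 2, axis=2)
                if d2.min() < min_separation ** 2:
                    ok = False
                    break
            if ok:
                placed = cand
                break
        if placed is None:
            raise RuntimeError(
                f"failed to place DNA copy {k} after {max_retries} retries")
        copy = duplex.copy()
        copy.positions = placed
        copy.chain_ids = np.array([f"{c}{k}" for c in duplex.chain_ids],
                                  dtype="U4")
        obstacles.append(placed)
        merged = merge_systems(merged, copy)
        merged.box = box
    merged.metadata["dna_copies"] = n_copies
    return merged


# ---------------------------------------------------------------------------
# restraint release
# ---------------------------------------------------------------------------

def release_restraint_protocol(fitted_system: CGSystem,
                               config: SimulationConfig,
                               inter_contact_mask=None,
                               arm_indices=None) -> Trajectory:
    """Continue a restrained run with the AFM restraint switched off.

    The structure relaxes under the native-structure-based potential alone.
    Per-frame inter-subunit Q-scores (over ``inter_contact_mask`` contacts,
    taken from the system metadata if not given) and hinge angles (from
    ``arm_indices`` metadata) are added to the trajectory logs.
    """
    from .analysis import qscore, hinge_angle_from_positions

    released = SimulationConfig(**dict(config.__dict__))
    released.kappa = 0.0
    released.reference_image = None
    traj = run_simulation(fitted_system, released)
    traj.logs["afm_restraint"] = np.zeros(traj.n_frames)

    mask = inter_contact_mask
    if mask is None:
        mask = fitted_system.metadata.get("interarm_contact_mask")
    arms = arm_indices
    if arms is None and "arm_a" in fitted_system.metadata:
        arms = (fitted_system.metadata["arm_a"],
                fitted_system.metadata["arm_b"])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        qs = [qscore(fitted_system.native_contacts[mask],
                     fitted_system.contact_r0[mask], frame)
              for frame in traj.positions]
        traj.logs["inter_subunit_q"] = np.asarray(qs)
    if arms is not None:
        ang = [hinge_angle_from_positions(frame, arms[0], arms[1])
               for frame in traj.positions]
        traj.logs["hinge_angle_deg"] = np.asarray(ang)
    return traj
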