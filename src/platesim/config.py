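"""Physical parameters, lattice scaling and unit conversion.

All quantities are stored in SI units.  The lattice Boltzmann solver works in
lattice units in which the grid spacing ``h``, the timestep ``dt`` and the
quiescent plasma density are all 1; :class:`UnitConverter` maps between the
two systems.

The timestep follows from the BGK relaxation time through

    dt = (tau - 1/2) h^2 / (3 nu),      nu = mu / rho,

which closes the viscosity relation mu = rho c_s^2 (tau - 1/2) dt with
c_s = (1/sqrt(3)) h/dt, so the configured plasma viscosity is reproduced
exactly by the fluid solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Boltzmann constant, J/K
KB = 1.380649e-23

_CONVERTIBLE_KINDS = ("length", "time", "velocity", "force", "density", "rate")


class StabilityError(ValueError):
    """Raised when a parameter choice violates a solver stability bound."""


def compute_timestep(tau_relax: float, h: float, nu: float) -> float:
    """Timestep (s) implied by relaxation time, grid spacing and viscosity.

    Parameters
    ----------
    tau_relax : dimensionless BGK relaxation time, must exceed 1/2.
    h : lattice spacing (m).
    nu : kinematic viscosity (m^2/s).
    """
    if tau_relax <= 0.5:
        raise StabilityError(f"tau_relax must exceed 0.5, got {tau_relax}")
    if h <= 0 or nu <= 0:
        raise ValueError("h and nu must be positive")
    return (tau_relax - 0.5) * h * h / (3.0 * nu)


def reynolds_number(gamma_shear: float, rho: float, a: float, mu: float) -> float:
    """Shear Reynolds number Re = gamma rho a^2 / mu of the platelet system."""
    if min(rho, a, mu) <= 0 or gamma_shear < 0:
        raise ValueError("parameters must be positive (gamma_shear >= 0)")
    return gamma_shear * rho * a * a / mu


@dataclass
class PhysicalParams:
    """Physical parameters of the platelet/plasma/adhesion system (SI).

    Defaults are the values used for the simulations this package reproduces:
    a resting human platelet modelled as an oblate spheroid of radius 1 um and
    aspect ratio 0.25 in blood plasma, with GPIb-alpha/vWF kinetics from flow
    chamber experiments.

    Notes
    -----
    * ``kon0`` defaults to the tabulated intrinsic cross-linking rate
      1e-5 1/s.  That value is implausibly small for an on-rate (bonds would
      essentially never form); it is kept as the documented default but every
      tethering preset overrides it.  See docs/methods.md.
    * ``gamma_rc`` (reactive compliance) and ``sigma_bond`` (bond spring
      constant) are not tabulated by the source model; the defaults are
      provisional flow-chamber-scale values and are ordinary config keys.
    """

    a: float = 1.0e-6                 # platelet major radius (m)
    lambda_ar: float = 0.25           # aspect ratio (dimensionless, <= 1)
    gamma_shear: float = 400.0        # shear rate (1/s)
    rho: float = 1023.9               # plasma density (kg/m^3)
    mu: float = 1.2e-3                # plasma viscosity (Pa s)
    E: float = 25.0e3                 # membrane elastic modulus (Pa)
    l0: float = 75.0e-9               # average initial spring length (m)
    dx_unit: float = 0.1e-6           # unit link length Delta-x (m)
    k_s: float = 6000.0               # global area constraint coefficient
    k_t: float = 6000.0               # local area constraint coefficient
    k_v: float = 6000.0               # volume constraint coefficient
    k0_bend_kBT: float = 200.0        # bending modulus in units of kB*T
    T: float = 300.0                  # temperature (K)
    kon0: float = 1.0e-5              # intrinsic on-rate (1/s); see Notes
    koff0: float = 3.45               # unstressed off-rate (1/s)
    gamma_rc: float = 0.0702e-9       # reactive compliance (m); provisional
    sigma_bond: float = 1.0e-5        # bond spring constant (N/m); provisional
    sigma_ts: float | None = None     # transition-state spring (N/m);
    #                                   defaults to sigma_bond (Dembo form)
    l_b: float = 128.0e-9             # equilibrium bond length (m)
    bind_radius: float = 128.0e-9     # formation test radius (m)
    F0_rep: float = 5.0e-19           # wall repulsion amplitude (N m)
    tau_rep: float = 2.0e9            # wall repulsion decay (1/m), 2000/um
    rho_vwf: float = 25.0e12          # wall vWF density (1/m^2), 25/um^2
    n_receptors: int = 10688          # GPIb-alpha receptors per platelet
    wall_shear_stress: float | None = None  # Pa; if set, overrides gamma_shear

    def __post_init__(self) -> None:
        for name in ("a", "lambda_ar", "rho", "mu", "E", "l0", "dx_unit",
                     "T", "koff0", "gamma_rc", "sigma_bond", "l_b",
                     "bind_radius", "tau_rep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lambda_ar > 1.0:
            raise ValueError("lambda_ar must be <= 1 (oblate or sphere)")
        if self.n_receptors < 0:
            raise ValueError("n_receptors must be non-negative")

    @property
    def nu(self) -> float:
        """Kinematic viscosity of plasma (m^2/s)."""
        return self.mu / self.rho

    @property
    def kBT(self) -> float:
        """Thermal energy (J)."""
        return KB * self.T

    @property
    def k0_bend(self) -> float:
        """Bending modulus (J)."""
        return self.k0_bend_kBT * self.kBT

    @property
    def k_spring(self) -> float:
        """Cytoskeleton spring stiffness k = E dx / 5 (N/m)."""
        return self.E * self.dx_unit / 5.0

    @property
    def effective_shear_rate(self) -> float:
        """Shear rate (1/s); derived from wall shear stress when that is set.

        Experiments are most naturally parameterized by the wall shear stress
        (3.0 / 4.0 dyn cm^-2 conditions); with stress set, gamma = stress/mu.
        """
        if self.wall_shear_stress is not None:
            return self.wall_shear_stress / self.mu
        return self.gamma_shear

    def reynolds(self) -> float:
        return reynolds_number(self.effective_shear_rate, self.rho, self.a, self.mu)


@dataclass
class LatticeScaling:
    """Lattice spacing/timestep/relaxation and derived conversion factors."""

    h: float = 0.2e-6            # lattice spacing (m)
    tau_relax: float = 1.379     # BGK relaxation time (dimensionless)
    nu: float = 1.2e-3 / 1023.9  # physical kinematic viscosity (m^2/s)
    rho: float = 1023.9          # physical density mapped to lattice rho=1

    def __post_init__(self) -> None:
        if self.tau_relax <= 0.5:
            raise StabilityError("tau_relax must exceed 0.5")
        if self.h <= 0 or self.nu <= 0 or self.rho <= 0:
            raise ValueError("h, nu, rho must be positive")

    @property
    def dt(self) -> float:
        """Timestep (s), dt = (tau - 1/2) h^2 / (3 nu)."""
        return compute_timestep(self.tau_relax, self.h, self.nu)

    # conversion factors: physical = lattice * factor
    @property
    def C_length(self) -> float:
        return self.h

    @property
    def C_time(self) -> float:
        return self.dt

    @property
    def C_velocity(self) -> float:
        return self.h / self.dt

    @property
    def C_density(self) -> float:
        return self.rho

    @property
    def C_mass(self) -> float:
        return self.rho * self.h ** 3

    @property
    def C_force(self) -> float:
        return self.C_mass * self.C_length / self.C_time ** 2

    @property
    def C_rate(self) -> float:
        return 1.0 / self.dt


class UnitConverter:
    """Convert scalar/array quantities between physical (SI) and lattice units."""

    def __init__(self, scaling: LatticeScaling):
        self.scaling = scaling
        self._factors = {
            "length": scaling.C_length,
            "time": scaling.C_time,
            "velocity": scaling.C_velocity,
            "force": scaling.C_force,
            "density": scaling.C_density,
            "rate": scaling.C_rate,
        }

    def to_lattice(self, value, kind: str):
        return value / self._factor(kind)

    def to_physical(self, value, kind: str):
        return value * self._factor(kind)

    def _factor(self, kind: str) -> float:
        try:
            return self._factors[kind]
        except KeyError:
            raise ValueError(
                f"unknown kind {kind!r}; expected one of {_CONVERTIBLE_KINDS}"
            ) from None


@dataclass
class ExperimentSettings:
    """Settings for the coupled experiments (domain, mesh, run control)."""

    grid_shape: tuple[int, int, int] = (80, 320, 80)   # 16 x 64 x 16 um at h=0.2 um
    n_vertices: int = 958
    n_receptor_sites: int = 5344       # each site carries 2 receptors
    centroid_height: float = 1.5e-6    # initial H (m)
    n_sub: int = 100                   # fluid steps between adhesion MC updates
    stiffness_scale: float = 1.0       # multiplies all membrane moduli
    v_pause_frac: float = 0.1
    min_pause_frames: int = 20
    smooth_frames: int = 11    # moving-average window for pause detection
    seed: int = 0


@dataclass
class SimulationConfig:
    """Bundle of physical parameters, lattice scaling and experiment settings."""

    physical: PhysicalParams = field(default_factory=PhysicalParams)
    lattice: LatticeScaling = field(default_factory=LatticeScaling)
    experiment: ExperimentSettings = field(default_factory=ExperimentSettings)

    def __post_init__(self) -> None:
        # keep lattice viscosity/density consistent with the plasma they model
        self.lattice.nu = self.physical.nu
        self.lattice.rho = self.physical.rho

    def converter(self) -> UnitConverter:
        return UnitConverter(self.lattice)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "physical": asdict(self.physical),
            "lattice": {"h": self.lattice.h, "tau_relax": self.lattice.tau_relax},
            "experiment": asdict(self.experiment),
        }
        data["experiment"]["grid_shape"] = list(self.experiment.grid_shape)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        phys = PhysicalParams(**data.get("physical", {}))
        lat = LatticeScaling(
            h=data.get("lattice", {}).get("h", 0.2e-6),
            tau_relax=data.get("lattice", {}).get("tau_relax", 1.379),
            nu=phys.nu,
            rho=phys.rho,
        )
        exp_data = dict(data.get("experiment", {}))
        if "grid_shape" in exp_data:
            exp_data["grid_shape"] = tuple(exp_data["grid_shape"])
        exp = ExperimentSettings(**exp_data)
        return cls(physical=phys, lattice=lat, experiment=exp)
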