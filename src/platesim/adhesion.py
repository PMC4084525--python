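"""Stochastic adhesive dynamics of GPIb-alpha / vWF tether bonds.

Receptor sites on the platelet surface (each carrying two GPIb-alpha
receptors) bind von Willebrand factor immobilized on the wall plane z=0.
Per Monte Carlo step of length dt each free site/ligand pair closer than the
bind radius forms a bond with probability P_f = 1 - exp(-k_on dt) and each
existing bond breaks with probability P_r = 1 - exp(-k_off dt), with

    k_off(F)  = koff0 exp(gamma_rc F / kB T)              (Bell, pure slip)
    k_on(x)   = kon0 exp(-sigma (x - l_b)^2 / (2 kB T))   (Dembo)

Steric rules: (i) a receptor site binds at most one vWF; (ii) a vWF binds
receptor(s) from at most four distinct sites.  Candidate pairs are processed
in a uniformly shuffled order each step to avoid index bias.  Bonds act as
linear springs of stiffness sigma and rest length l_b.

The same rate laws drive GPIb-alpha/vWF/GPIb-alpha bridging between two
platelets, with the partner platelet's receptor sites acting as the ligands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class KineticParams:
    """Bond kinetic and mechanical parameters (SI)."""

    kon0: float                # intrinsic on-rate (1/s)
    koff0: float               # unstressed off-rate (1/s)
    gamma_rc: float            # reactive compliance (m)
    sigma_bond: float          # bond spring constant (N/m)
    l_b: float                 # equilibrium bond length (m)
    bind_radius: float         # formation test radius (m)
    kBT: float                 # thermal energy (J)
    sigma_ts: float | None = None  # transition-state spring for formation
    #                                (N/m); defaults to sigma_bond

    def __post_init__(self) -> None:
        for name in ("kon0", "koff0", "gamma_rc", "sigma_bond", "l_b",
                     "bind_radius", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_ts is None:
            self.sigma_ts = self.sigma_bond
        elif self.sigma_ts <= 0:
            raise ValueError("sigma_ts must be positive")

    @classmethod
    def from_physical(cls, phys) -> "KineticParams":
        return cls(kon0=phys.kon0, koff0=phys.koff0, gamma_rc=phys.gamma_rc,
                   sigma_bond=phys.sigma_bond, l_b=phys.l_b,
                   bind_radius=phys.bind_radius, kBT=phys.kBT,
                   sigma_ts=getattr(phys, "sigma_ts", None))


def bell_off_rate(F_b, kp: KineticParams):
    """Force-dependent dissociation rate koff0 exp(gamma F / kBT) (slip bond)."""
    F_b = np.asarray(F_b, dtype=float)
    return kp.koff0 * np.exp(kp.gamma_rc * F_b / kp.kBT)


def dembo_on_rate(x_b, kp: KineticParams):
    """Length-dependent formation rate kon0 exp(-sigma_ts (x-l_b)^2 / 2 kBT).

    The transition-state spring sigma_ts defaults to the mechanical bond
    spring sigma; presets with stiffened mechanical springs keep a soft
    sigma_ts so the formation window stays at its physical width."""
    x_b = np.asarray(x_b, dtype=float)
    d = x_b - kp.l_b
    return kp.kon0 * np.exp(-kp.sigma_ts * d * d / (2.0 * kp.kBT))


def binding_probabilities(kon, koff, dt: float):
    """Per-step formation/rupture probabilities (P_f, P_r) for interval dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return 1.0 - np.exp(-np.asarray(kon) * dt), 1.0 - np.exp(-np.asarray(koff) * dt)


def bond_force(receptor_pos: np.ndarray, ligand_pos: np.ndarray,
               kp: KineticParams):
    """Spring force sigma (x_b - l_b) on the receptor end, directed along the
    bond; tensile (toward the ligand) when stretched.  Returns (force vectors,
    lengths, signed magnitudes)."""
    d = np.atleast_2d(ligand_pos) - np.atleast_2d(receptor_pos)
    x_b = np.linalg.norm(d, axis=1)
    x_safe = np.where(x_b > 0, x_b, 1.0)
    mag = kp.sigma_bond * (x_b - kp.l_b)
    fvec = (mag / x_safe)[:, None] * d
    return fvec, x_b, mag


def wall_repulsion(separation, F0_rep: float, tau_rep: float,
                   eps_min: float = 1.0e-9):
    """Short-range wall contact force magnitude F0 tau e^(-tau e)/(1-e^(-tau e)).

    Separations below ``eps_min`` (default 1 nm) are clamped there: the force
    is already enormous at that range and the expression diverges at zero.
    """
    eps = np.maximum(np.asarray(separation, dtype=float), eps_min)
    ex = np.exp(-tau_rep * eps)
    return F0_rep * tau_rep * ex / (1.0 - ex)


@dataclass
class LigandField:
    """Immobilized vWF molecules on the wall plane z=0.

    Positions are a uniform jittered grid realising the configured surface
    density (default 25 um^-2); ``bound_count`` tracks rule (ii) occupancy
    (at most ``max_sites_per_ligand`` receptor sites per vWF).
    """

    positions: np.ndarray                  # (L, 3), z = 0
    max_sites_per_ligand: int = 4
    bound_count: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bound_count is None:
            self.bound_count = np.zeros(len(self.positions), dtype=int)

    @classmethod
    def uniform(cls, lx: float, ly: float, density: float,
                seed: int | None = None) -> "LigandField":
        """Uniformly random vWF positions on [0,lx)x[0,ly) at given density."""
        rng = np.random.default_rng(seed)
        n = int(round(density * lx * ly))
        pos = np.zeros((n, 3))
        pos[:, 0] = rng.random(n) * lx
        pos[:, 1] = rng.random(n) * ly
        return cls(positions=pos)


@dataclass
class BondState:
    """Currently formed receptor-site/ligand bonds.

    ``site_bond`` maps receptor site -> ligand id (-1 when free), enforcing
    rule (i); per-bond formation times support lifetime statistics.
    """

    n_sites: int
    site_bond: np.ndarray = field(default=None)  # type: ignore[assignment]
    formation_time: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.site_bond is None:
            self.site_bond = np.full(self.n_sites, -1, dtype=int)
        if self.formation_time is None:
            self.formation_time = np.full(self.n_sites, np.nan)

    @property
    def bound_sites(self) -> np.ndarray:
        return np.flatnonzero(self.site_bond >= 0)

    @property
    def n_bonds(self) -> int:
        return int(np.count_nonzero(self.site_bond >= 0))


def bond_forces_on_sites(bonds: BondState, site_positions: np.ndarray,
                         ligands: LigandField, kp: KineticParams):
    """Adhesion force vector per bound site (and lengths/magnitudes)."""
    idx = bonds.bound_sites
    if len(idx) == 0:
        return idx, np.empty((0, 3)), np.empty(0), np.empty(0)
    fvec, x_b, mag = bond_force(site_positions[idx],
                                ligands.positions[bonds.site_bond[idx]], kp)
    return idx, fvec, x_b, mag


def mc_update(
    bonds: BondState,
    site_positions: np.ndarray,
    ligands: LigandField,
    kp: KineticParams,
    dt: float,
    rng: np.random.Generator,
    t: float = 0.0,
    event_log: list | None = None,
) -> BondState:
    """One Monte Carlo adhesion step: rupture tests then formation tests.

    Formation candidates are all free-site/unsaturated-ligand pairs within
    the bind radius, visited in a uniformly shuffled order so competition for
    rule-(ii) slots carries no index bias.  Deterministic given ``rng``.
    """
    # --- rupture ---------------------------------------------------------
    idx, fvec, x_b, mag = bond_forces_on_sites(bonds, site_positions, ligands, kp)
    if len(idx):
        tension = np.maximum(mag, 0.0)       # compression does not speed rupture
        _, P_r = binding_probabilities(0.0, bell_off_rate(tension, kp), dt)
        broke = rng.random(len(idx)) < P_r
        for s in idx[broke]:
            lig = bonds.site_bond[s]
            ligands.bound_count[lig] -= 1
            if event_log is not None:
                event_log.append((t, "break", int(s), int(lig),
                                  float(np.linalg.norm(
                                      ligands.positions[lig] - site_positions[s])),
                                  float(kp.sigma_bond * (np.linalg.norm(
                                      ligands.positions[lig] - site_positions[s])
                                      - kp.l_b))))
            bonds.site_bond[s] = -1
            bonds.formation_time[s] = np.nan

    # --- formation -------------------------------------------------------
    free = np.flatnonzero(bonds.site_bond < 0)
    if len(free) and len(ligands.positions):
        tree = cKDTree(ligands.positions)
        pairs = tree.query_ball_point(site_positions[free], kp.bind_radius)
        cand_s, cand_l = [], []
        for i, ligs in enumerate(pairs):
            for l in ligs:
                cand_s.append(free[i])
                cand_l.append(l)
        if cand_s:
            cand_s = np.asarray(cand_s)
            cand_l = np.asarray(cand_l)
            order = rng.permutation(len(cand_s))
            dist = np.linalg.norm(
                site_positions[cand_s] - ligands.positions[cand_l], axis=1)
            P_f, _ = binding_probabilities(dembo_on_rate(dist, kp), 0.0, dt)
            draws = rng.random(len(cand_s))
            for j in order:
                s, l = cand_s[j], cand_l[j]
                if bonds.site_bond[s] >= 0:
                    continue  # rule (i): site already took a vWF this step
                if ligands.bound_count[l] >= ligands.max_sites_per_ligand:
                    continue  # rule (ii): vWF saturated
                if draws[j] < P_f[j]:
                    bonds.site_bond[s] = l
                    bonds.formation_time[s] = t
                    ligands.bound_count[l] += 1
                    if event_log is not None:
                        event_log.append((t, "form", int(s), int(l),
                                          float(dist[j]),
                                          float(kp.sigma_bond * (dist[j] - kp.l_b))))
    return bonds


def check_rules(bonds: BondState, ligands: LigandField) -> None:
    """Assert steric-rule invariants; raise on violation."""
    bound = bonds.site_bond[bonds.site_bond >= 0]
    counts = np.bincount(bound, minlength=len(ligands.positions))
    if not np.array_equal(counts, ligands.bound_count):
        raise AssertionError("ligand occupancy bookkeeping inconsistent")
    if np.any(counts > ligands.max_sites_per_ligand):
        raise AssertionError("rule (ii) violated: vWF bound by > 4 sites")
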