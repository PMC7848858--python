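"""Conductance-based compartmental neuron model.

The cell is a spherical soma coupled to two thin passive dendrites, each
discretized into four iso-potential cylindrical compartments.  The soma
carries Hodgkin–Huxley sodium and delayed-rectifier potassium channels (the
V_T-shifted kinetics below); the dendrites carry only leak, so they cannot
spike — their only non-linearity is the saturation of synaptic driving force.
Synapses are conductance-based with reversal at 0 mV: each presynaptic spike
makes the synaptic conductance jump by ``g_max`` and decay exponentially with
τ_s = 1 ms.

Membrane equations (per compartment, conventional signs)::

    C_m dV/dt = -g_L (V - E_L) - ḡ_Na m³h (V - E_Na) - ḡ_K n⁴ (V - E_K)
                + I_axial + g_s (E_s - V)

with the active terms present only at the soma.  Axial currents follow from
cylinder geometry and the axial resistivity R_a.

Integration: exponential Euler for the gating variables, backward (implicit)
Euler for the voltage vector.  Because every membrane current is of
conductance form, the voltage update is a linear solve; ordering the
compartments tip-to-tip (dendrite 1 reversed, soma, dendrite 2) makes the
system tridiagonal.

Internally the model uses a consistent mV / ms / µS / nF unit system (so
currents are in nA); all public interfaces use the customary units stated in
the docstrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "Morphology",
    "MembraneParams",
    "Synapse",
    "NeuronModel",
    "SimResult",
    "SimulationDiverged",
    "build_neuron",
    "hh_rates",
    "simulate",
    "max_somatic_depolarisation",
    "detect_spikes",
]

_UM = 1e-4  # cm per µm


@dataclass(frozen=True)
class Morphology:
    """Soma + two-dendrite geometry (µm).

    Defaults: 10 µm spherical soma; two 400 µm × 0.4 µm dendritic cylinders,
    four compartments each, attached to the soma at one end.
    """

    soma_diameter_um: float = 10.0
    dendrite_length_um: float = 400.0
    dendrite_diameter_um: float = 0.4
    n_dendrites: int = 2
    compartments_per_dendrite: int = 4

    def __post_init__(self) -> None:
        for name in ("soma_diameter_um", "dendrite_length_um", "dendrite_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_dendrites < 1 or self.compartments_per_dendrite < 1:
            raise ValueError("need at least one dendrite with one compartment")

    @property
    def n_compartments(self) -> int:
        return 1 + self.n_dendrites * self.compartments_per_dendrite

    @property
    def segment_length_um(self) -> float:
        return self.dendrite_length_um / self.compartments_per_dendrite


@dataclass(frozen=True)
class MembraneParams:
    """Membrane and channel parameters.

    ``gNa_mS_per_cm2`` defaults to 100 (the table value); the sub-threshold
    experiments set it to 0 and the spiking experiments to 650.  ``Ra_ohm_cm``
    is the axial resistivity: the one parameter with no printed value, it is
    calibrated so that 100 nS of clustered distal input peaks at −54 mV at the
    soma (see docs/methods.md, which also discusses the leak default).
    """

    Cm_uF_per_cm2: float = 1.0
    gL_mS_per_cm2: float = 0.2
    gNa_mS_per_cm2: float = 100.0
    gK_mS_per_cm2: float = 30.0
    EL_mV: float = -65.0
    ENa_mV: float = 50.0
    EK_mV: float = -90.0
    Es_mV: float = 0.0
    VT_mV: float = -50.0
    tau_s_ms: float = 1.0
    Ra_ohm_cm: float = 48.5

    def __post_init__(self) -> None:
        for name in ("Cm_uF_per_cm2", "gL_mS_per_cm2", "gNa_mS_per_cm2",
                     "gK_mS_per_cm2", "tau_s_ms", "Ra_ohm_cm"):
            if getattr(self, name) < 0 or (name in ("Cm_uF_per_cm2", "tau_s_ms",
                                                    "Ra_ohm_cm") and getattr(self, name) == 0):
                raise ValueError(f"{name} must be non-negative and finite, got {getattr(self, name)}")


@dataclass(frozen=True)
class Synapse:
    """A conductance synapse on one compartment.

    Either give ``compartment`` directly (0 = soma, then dendrite 0 proximal
    to distal, then dendrite 1), or a (``dendrite``, ``distance_um``) pair;
    a distance of 350 µm lands in the fourth (300–400 µm) compartment.
    """

    gmax_nS: float
    compartment: int | None = None
    dendrite: int | None = None
    distance_um: float | None = None

    def __post_init__(self) -> None:
        if self.gmax_nS < 0:
            raise ValueError(f"gmax_nS must be >= 0, got {self.gmax_nS}")
        if self.compartment is None and (self.dendrite is None or self.distance_um is None):
            raise ValueError("give either compartment or (dendrite, distance_um)")

    def resolve(self, morph: Morphology) -> int:
        if self.compartment is not None:
            if not 0 <= self.compartment < morph.n_compartments:
                raise ValueError(
                    f"compartment {self.compartment} outside 0..{morph.n_compartments - 1}"
                )
            return self.compartment
        if not 0 <= self.dendrite < morph.n_dendrites:
            raise ValueError(f"dendrite {self.dendrite} outside 0..{morph.n_dendrites - 1}")
        if not 0 <= self.distance_um <= morph.dendrite_length_um:
            raise ValueError(
                f"distance {self.distance_um} µm outside the {morph.dendrite_length_um} µm dendrite"
            )
        seg = min(
            int(self.distance_um // morph.segment_length_um),
            morph.compartments_per_dendrite - 1,
        )
        return 1 + self.dendrite * morph.compartments_per_dendrite + seg


class SimulationDiverged(RuntimeError):
    """Raised when the integrator produces a non-finite voltage."""


@dataclass(frozen=True)
class NeuronModel:
    """Assembled ODE system: geometry-derived constants plus synapse list."""

    morphology: Morphology
    params: MembraneParams
    synapses: tuple[Synapse, ...]
    areas_cm2: np.ndarray = field(repr=False)
    axial_uS: np.ndarray = field(repr=False)  # coupling matrix, off-diagonal >= 0

    @property
    def n_compartments(self) -> int:
        return self.morphology.n_compartments

    def synapse_compartments(self) -> list[int]:
        return [s.resolve(self.morphology) for s in self.synapses]


def build_neuron(
    morph: Morphology | None = None,
    params: MembraneParams | None = None,
    synapses: Sequence[Synapse] = (),
) -> NeuronModel:
    """Compute areas and axial couplings and assemble the model.

    The soma couples to the first compartment of each dendrite through half a
    segment of axial resistance (soma treated as an iso-potential point);
    adjacent dendritic compartments couple centre-to-centre through a full
    segment.
    """
    morph = morph or Morphology()
    params = params or MembraneParams()
    ncomp = morph.n_compartments

    soma_area = np.pi * (morph.soma_diameter_um * _UM) ** 2  # sphere: π d²
    seg_area = (
        np.pi * morph.dendrite_diameter_um * _UM * morph.segment_length_um * _UM
    )
    areas = np.array([soma_area] + [seg_area] * (ncomp - 1))

    a_cm = morph.dendrite_diameter_um * _UM / 2
    l_cm = morph.segment_length_um * _UM
    g_seg = np.pi * a_cm**2 / (params.Ra_ohm_cm * l_cm) * 1e6  # µS
    g_soma = np.pi * a_cm**2 / (params.Ra_ohm_cm * l_cm / 2) * 1e6

    axial = np.zeros((ncomp, ncomp))
    for d in range(morph.n_dendrites):
        base = 1 + d * morph.compartments_per_dendrite
        pairs = [(0, base, g_soma)]
        pairs += [
            (base + k, base + k + 1, g_seg)
            for k in range(morph.compartments_per_dendrite - 1)
        ]
        for i, j, g in pairs:
            axial[i, j] += g
            axial[j, i] += g
            axial[i, i] -= g
            axial[j, j] -= g

    for s in synapses:
        s.resolve(morph)  # validate placements early

    return NeuronModel(
        morphology=morph,
        params=params,
        synapses=tuple(synapses),
        areas_cm2=areas,
        axial_uS=axial,
    )


def _exprel_inv(x: np.ndarray | float) -> np.ndarray | float:
    """x / (exp(x) - 1) with the removable singularity at 0 handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):
        out = np.where(small, 1.0 - x / 2.0, safe / np.expm1(safe))
    return out if out.ndim else float(out)


def hh_rates(V_mV: float | np.ndarray, VT_mV: float = -50.0) -> dict[str, np.ndarray | float]:
    """V_T-shifted Hodgkin–Huxley opening/closing rates (ms⁻¹).

    With v = V − V_T::

        α_m = 0.32 (13−v) / (exp((13−v)/4) − 1)    β_m = 0.28 (v−40) / (exp((v−40)/5) − 1)
        α_h = 0.128 exp((17−v)/18)                  β_h = 4 / (1 + exp((40−v)/5))
        α_n = 0.032 (15−v) / (exp((15−v)/5) − 1)    β_n = 0.5 exp((10−v)/40)

    The removable singularities (v = 13 for m, v = 15 for n, v = 40 for β_m)
    are evaluated by their limits.
    """
    v = np.asarray(V_mV, dtype=float) - VT_mV
    rates = {
        "alpha_m": 0.32 * 4.0 * _exprel_inv((13.0 - v) / 4.0),
        "beta_m": 0.28 * 5.0 * _exprel_inv((v - 40.0) / 5.0),
        "alpha_h": 0.128 * np.exp((17.0 - v) / 18.0),
        "beta_h": 4.0 / (1.0 + np.exp((40.0 - v) / 5.0)),
        "alpha_n": 0.032 * 5.0 * _exprel_inv((15.0 - v) / 5.0),
        "beta_n": 0.5 * np.exp((10.0 - v) / 40.0),
    }
    if np.ndim(V_mV) == 0:
        rates = {k: float(val) for k, val in rates.items()}
    return rates


@dataclass(frozen=True)
class SimResult:
    """Time grid (ms), per-compartment voltages (mV) and somatic spikes."""

    t_ms: np.ndarray
    V_mV: np.ndarray  # shape (n_times, n_compartments); column 0 is the soma
    spike_times_ms: tuple[float, ...]
    rest_mV: float

    @property
    def V_soma(self) -> np.ndarray:
        return self.V_mV[:, 0]

    def traces_to_csv(self, path) -> None:
        """Tidy long-format voltage traces: time_ms, compartment_id, V_mV."""
        import pandas as pd

        n_t, n_c = self.V_mV.shape
        df = pd.DataFrame(
            {
                "time_ms": np.repeat(self.t_ms, n_c),
                "compartment_id": np.tile(np.arange(n_c), n_t),
                "V_mV": self.V_mV.ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")

    def spikes_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"spike_time_ms": list(self.spike_times_ms)}).to_csv(
            path, index=False, float_format="%.3f"
        )


def detect_spikes(
    t_ms: np.ndarray, v_soma: np.ndarray, level_mV: float = -20.0, min_sep_ms: float = 2.0
) -> tuple[float, ...]:
    """Upward crossings of ``level_mV`` at least ``min_sep_ms`` apart."""
    above = v_soma > level_mV
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    out: list[float] = []
    for i in idx:
        ti = float(t_ms[i])
        if not out or ti - out[-1] >= min_sep_ms:
            out.append(ti)
    return tuple(out)


def simulate(
    model: NeuronModel,
    spike_times_ms: Sequence[Sequence[float]] | None = None,
    T_ms: float = 250.0,
    dt_ms: float = 0.025,
    record: bool = True,
) -> SimResult:
    """Integrate the model under the given presynaptic spike trains.

    ``spike_times_ms[k]`` lists the presynaptic spike times of the k-th
    synapse in ``model.synapses``.  Each spike adds ``gmax_nS`` to that
    synapse's conductance at the grid point nearest the spike time.

    Raises ``SimulationDiverged`` (naming the first bad compartment and time)
    if any voltage becomes non-finite.
    """
    if dt_ms <= 0 or T_ms <= 0:
        raise ValueError(f"need positive dt and T, got dt={dt_ms}, T={T_ms}")
    p = model.params
    ncomp = model.n_compartments
    nper = model.morphology.compartments_per_dendrite

    Cm = model.areas_cm2 * p.Cm_uF_per_cm2 * 1e3  # nF
    gl = p.gL_mS_per_cm2 * 1e-3 * model.areas_cm2 * 1e6  # µS
    gNa_max = p.gNa_mS_per_cm2 * 1e-3 * model.areas_cm2[0] * 1e6
    gK_max = p.gK_mS_per_cm2 * 1e-3 * model.areas_cm2[0] * 1e6

    # tridiagonal ordering: dendrite 0 tip->root, soma, dendrite 1 root->tip
    # (only valid for <= 2 dendrites; fall back to dense otherwise)
    tridiag = model.morphology.n_dendrites <= 2
    if tridiag:
        perm = list(range(nper, 0, -1)) + [0] + list(range(nper + 1, ncomp))
        perm = np.asarray(perm)
        inv = np.argsort(perm)
        A = model.axial_uS[np.ix_(perm, perm)]
        # voltage system is M = diag(...) - A, so off-diagonals flip sign
        upper = np.concatenate(([0.0], -np.diagonal(A, 1)))
        lower = np.concatenate((-np.diagonal(A, -1), [0.0]))
        diag_axial = np.diagonal(A).copy()

    n_steps = int(round(T_ms / dt_ms))
    syn_comp = np.asarray(model.synapse_compartments(), dtype=int)

    jumps: dict[int, np.ndarray] = {}
    if spike_times_ms is not None:
        if len(spike_times_ms) != len(model.synapses):
            raise ValueError(
                f"{len(spike_times_ms)} spike trains for {len(model.synapses)} synapses"
            )
        for k, train in enumerate(spike_times_ms):
            for t in train:
                if not 0 <= t <= T_ms:
                    raise ValueError(f"spike at {t} ms outside [0, {T_ms}] ms")
                step = int(round(t / dt_ms))
                vec = jumps.setdefault(step, np.zeros(ncomp))
                vec[syn_comp[k]] += model.synapses[k].gmax_nS * 1e-3  # µS

    V = np.full(ncomp, p.EL_mV)
    r = hh_rates(V[0], p.VT_mV)
    m = r["alpha_m"] / (r["alpha_m"] + r["beta_m"])
    h = r["alpha_h"] / (r["alpha_h"] + r["beta_h"])
    ngate = r["alpha_n"] / (r["alpha_n"] + r["beta_n"])

    gs = np.zeros(ncomp)
    decay = np.exp(-dt_ms / p.tau_s_ms)
    if record:
        out = np.empty((n_steps + 1, ncomp))
        out[0] = V
    vsoma = np.empty(n_steps + 1)
    vsoma[0] = V[0]

    cm_dt = Cm / dt_ms
    for k in range(1, n_steps + 1):
        vec = jumps.get(k - 1)
        if vec is not None:
            gs = gs + vec
        r = hh_rates(V[0], p.VT_mV)
        am, bm = r["alpha_m"], r["beta_m"]
        ah, bh = r["alpha_h"], r["beta_h"]
        an, bn = r["alpha_n"], r["beta_n"]
        m = am / (am + bm) + (m - am / (am + bm)) * np.exp(-dt_ms * (am + bm))
        h = ah / (ah + bh) + (h - ah / (ah + bh)) * np.exp(-dt_ms * (ah + bh))
        ngate = an / (an + bn) + (ngate - an / (an + bn)) * np.exp(-dt_ms * (an + bn))

        g_na = gNa_max * m**3 * h
        g_k = gK_max * ngate**4
        diag_extra = gl + gs
        rhs = cm_dt * V + gl * p.EL_mV + gs * p.Es_mV
        diag_extra = diag_extra.copy()
        diag_extra[0] += g_na + g_k
        rhs[0] += g_na * p.ENa_mV + g_k * p.EK_mV

        if tridiag:
            ab = np.empty((3, ncomp))
            ab[0] = upper
            ab[1] = (cm_dt + diag_extra)[perm] - diag_axial
            ab[2] = lower
            V = solve_banded((1, 1), ab, rhs[perm])[inv]
        else:
            M = np.diag(cm_dt + diag_extra) - model.axial_uS
            V = np.linalg.solve(M, rhs)

        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise SimulationDiverged(
                f"non-finite voltage in compartment {bad} at t = {k * dt_ms:.3f} ms"
            )
        if record:
            out[k] = V
        vsoma[k] = V[0]
        gs = gs * decay

    t = np.arange(n_steps + 1) * dt_ms
    spikes = detect_spikes(t, vsoma)
    return SimResult(
        t_ms=t,
        V_mV=out if record else vsoma[:, None],
        spike_times_ms=spikes,
        rest_mV=p.EL_mV,
    )


def max_somatic_depolarisation(result: SimResult) -> float:
    """Peak somatic voltage above rest, in mV."""
    return float(result.V_soma.max() - result.rest_mV)
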