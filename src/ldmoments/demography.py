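"""Demographic models and expected LD-decay curves.

A :class:`DemographicModel` is a forward-time sequence of epochs (constant or
exponentially changing relative sizes, constant scaled migration matrix) and
discrete events (splits, admixture pulses, marginalization).  Expected
statistics are obtained by integrating the scaled moment ODE

    dy/dT = (D_nu(T) + M_mtilde + R_rho/2 + U_theta/2) y

through the model with a Crank-Nicolson scheme, starting from the ancestral
single-population equilibrium (or a user-supplied initial vector).  Time is
measured in units of ``2 N_ref`` generations.

Expected LD-decay curves evaluate the model once per recombination-distance
bin, using ``rho = 4 N_ref r`` at the geometric mean of the bin edges, and
optionally normalize two-locus rows by ``pi2`` of a chosen population and
heterozygosity rows by that population's ``H`` (sigma_d^2-style statistics,
whose value is independent of the overall mutation rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .basis import (
    BasisError,
    MomentBasis,
    MomentLabel,
    StatisticVector,
    build_basis,
    evaluate_state,
    marginalize,
)
from .events import apply_admixture, apply_split
from .operators import (EvolutionOperator, OperatorError, RateParameters, assemble,
                        assemble_dense)


class DemographyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# equilibrium and integration
# ---------------------------------------------------------------------------


def equilibrium(params: RateParameters, basis: MomentBasis) -> StatisticVector:
    """Stationary statistic vector: solves A y = 0 with the ONE entry pinned to 1."""
    if params.theta <= 0:
        raise DemographyError("equilibrium requires theta > 0 (mutation source)")
    A = assemble_dense(params)
    n = basis.size
    one = n - 1  # ONE is the last basis entry
    sub = A[:one, :one]
    rhs = -A[:one, one]
    try:
        y = scipy.linalg.solve(sub, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise DemographyError(f"singular moment system at equilibrium: {exc}") from exc
    return StatisticVector(basis, np.concatenate([y, [1.0]]))


def default_dt(duration: float) -> float:
    return min(1e-3, duration / 50.0) if duration > 0 else 1e-3


def integrate(
    y0: StatisticVector,
    params: RateParameters | Callable[[float], RateParameters],
    T: float,
    dt: float | None = None,
) -> StatisticVector:
    """Crank-Nicolson integration of the affine moment system for duration T.

    ``params`` may be a constant :class:`RateParameters` or a callable of the
    elapsed scaled time (evaluated at step midpoints for second-order
    accuracy).  The ONE entry is preserved exactly.
    """
    if T < 0:
        raise DemographyError("duration must be >= 0")
    if T == 0:
        return y0.copy()
    if dt is None:
        dt = default_dt(T)
    if dt <= 0:
        raise DemographyError("dt must be > 0")
    basis = y0.basis
    n_steps = max(1, int(math.ceil(T / dt)))
    h = T / n_steps
    y = y0.values.copy()
    n = basis.size
    eye = np.eye(n)
    constant = not callable(params)
    lu = None
    forward = None
    for step in range(n_steps):
        if lu is None or not constant:
            p = params if constant else params((step + 0.5) * h)
            A = assemble_dense(p)
            lu = scipy.linalg.lu_factor(eye - (h / 2.0) * A)
            forward = eye + (h / 2.0) * A
        y = scipy.linalg.lu_solve(lu, forward @ y)
        if not np.all(np.isfinite(y)):
            raise DemographyError(
                f"integration produced non-finite values at step {step + 1}/{n_steps}"
            )
    return StatisticVector(basis, y)


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------


SizeSpec = float | tuple[float, float] | Callable[[float], float]


@dataclass
class Epoch:
    """A period of continuous dynamics.

    ``duration`` is in units of 2*N_ref generations.  ``sizes`` maps each
    live population to a relative size nu (a number, a ``(start, end)`` pair
    for exponential change, or a callable of within-epoch scaled time).
    ``migration`` maps ``(source, dest)`` to the scaled rate
    ``mtilde = 2 N_ref m``.
    """

    duration: float
    sizes: dict[str, SizeSpec] | float = 1.0
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    dt: float | None = None

    def size_at(self, pop: str, t: float) -> float:
        spec = self.sizes if not isinstance(self.sizes, dict) else self.sizes.get(pop)
        if spec is None:
            raise DemographyError(f"epoch does not specify a size for {pop!r}")
        if callable(spec):
            return float(spec(t))
        if isinstance(spec, tuple):
            start, end = spec
            if self.duration == 0:
                return float(end)
            return float(start * (end / start) ** (t / self.duration))
        return float(spec)

    def is_constant(self) -> bool:
        if not isinstance(self.sizes, dict):
            return True
        return all(not callable(s) and not isinstance(s, tuple) for s in self.sizes.values())


@dataclass
class Split:
    parent: str
    children: tuple[str, str]


@dataclass
class Admixture:
    source1: str
    source2: str
    fraction: float
    child: str
    replace: bool = False


@dataclass
class Marginalize:
    population: str


@dataclass
class PulseInto:
    """Admixture pulse into an existing population (population set unchanged)."""

    source: str
    dest: str
    fraction: float


Event = Epoch | Split | Admixture | Marginalize | PulseInto


@dataclass
class DemographicModel:
    """Forward-time demographic model on a reference size ``N_ref``.

    The model starts with a single root population at equilibrium (unless
    ``initial`` is supplied) and proceeds through ``events`` in order.
    ``theta = 4 N_ref u`` sets the mutation source; a value of 0 is allowed
    only with an explicit initial vector.
    """

    N_ref: float
    events: Sequence[Event]
    root: str = "anc"
    theta: float = 1e-3
    initial: Callable[[float], StatisticVector] | StatisticVector | None = None

    def _params(self, epoch: Epoch, pops, rho: float, t: float) -> RateParameters:
        P = len(pops.labels)
        nu = np.array([epoch.size_at(p, t) for p in pops.labels])
        mig = np.zeros((P, P))
        for (src, dst), rate in epoch.migration.items():
            mig[pops.index(src), pops.index(dst)] = rate
        return RateParameters(nu=nu, mig=mig, rho=rho, theta=self.theta)

    def evaluate(self, rho: float = 0.0) -> StatisticVector:
        """Present-day expected statistics for a given scaled recombination rate."""
        basis = build_basis([self.root])
        if self.initial is not None:
            y = self.initial(rho) if callable(self.initial) else self.initial.copy()
            if len(y.basis.pops) != 1:
                basis = y.basis
        else:
            first = next((e for e in self.events if isinstance(e, Epoch)), None)
            if first is None:
                raise DemographyError(
                    "a model without an explicit initial vector needs at least one epoch"
                )
            params = self._params(first, basis.pops, rho, 0.0)
            y = equilibrium(params, basis)
        for event in self.events:
            if isinstance(event, Epoch):
                pops = y.basis.pops
                if event.is_constant():
                    params = self._params(event, pops, rho, 0.0)
                else:
                    params = lambda t, e=event, p=pops: self._params(e, p, rho, t)
                y = integrate(y, params, event.duration, dt=event.dt)
            elif isinstance(event, Split):
                y = apply_split(y, event.parent, event.children)
            elif isinstance(event, Admixture):
                y = apply_admixture(
                    y,
                    event.source1,
                    event.source2,
                    event.fraction,
                    event.child,
                    replace=event.replace,
                )
            elif isinstance(event, PulseInto):
                from .events import pulse_migration

                y = pulse_migration(y, event.source, event.dest, event.fraction)
            elif isinstance(event, Marginalize):
                y = marginalize(y, event.population)
            else:  # pragma: no cover
                raise DemographyError(f"unknown event {event!r}")
        return y

    def final_populations(self) -> list[str]:
        return list(self.evaluate_populations())

    def evaluate_populations(self) -> tuple[str, ...]:
        pops = (self.initial.basis.pops.labels if isinstance(self.initial, StatisticVector)
                else (self.root,))
        pops = list(pops)
        for event in self.events:
            if isinstance(event, Split):
                pops = [event.children[0] if p == event.parent else p for p in pops]
                pops.append(event.children[1])
            elif isinstance(event, Admixture):
                pops.append(event.child)
                if event.replace:
                    pops.remove(event.source2)
            elif isinstance(event, Marginalize):
                pops.remove(event.population)
        return tuple(pops)


# ---------------------------------------------------------------------------
# LD decay curves
# ---------------------------------------------------------------------------


@dataclass
class LDDecayCurve:
    """Expected (or observed) statistics per recombination-distance bin."""

    bin_edges: np.ndarray  # per-generation r, length n_bins + 1, strictly increasing
    labels: list[str]
    values: np.ndarray  # (n_bins, n_labels)
    normalization: str = "raw"

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise DemographyError("bin edges must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "bin_left", self.bin_edges[:-1])
        df.insert(1, "bin_right", self.bin_edges[1:])
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


R_VALIDITY_LIMIT = 0.1  # loosely linked loci need higher-order terms


def normalize_vector(
    vec: StatisticVector, norm_pop: str
) -> tuple[list[str], np.ndarray]:
    """sigma_d^2-style normalization: LD rows by pi2 of norm_pop, H rows by H."""
    basis = vec.basis
    i = basis.pops.index(norm_pop)
    pi2_norm = vec[MomentLabel("pi2", ((i, i), (i, i)))]
    h_norm = vec[MomentLabel("H", (i, i))]
    labels, values = [], []
    for lbl, val in zip(basis.labels, vec.values):
        if lbl.family == "ONE":
            continue
        denom = h_norm if lbl.family == "H" else pi2_norm
        labels.append(lbl.to_string())
        values.append(val / denom)
    return labels, np.array(values)


def expected_curves(
    model: DemographicModel,
    r_bins: Sequence[float],
    normalization: str = "raw",
) -> LDDecayCurve:
    """Model-expected binned statistics over recombination-distance bins.

    Each bin ``[r_k, r_{k+1})`` is represented by the geometric mean of its
    edges, mapped to ``rho = 4 N_ref r``.  ``normalization`` is either
    ``"raw"`` or a population label whose ``pi2`` (and ``H``) normalize the
    rows.
    """
    edges = np.asarray(r_bins, dtype=float)
    if np.any(edges < 0) or np.any(np.diff(edges) <= 0):
        raise DemographyError("r bins must be non-negative and strictly increasing")
    if edges[-1] >= R_VALIDITY_LIMIT:
        raise DemographyError(
            f"bins extend to r >= {R_VALIDITY_LIMIT}; the leading-order moment "
            "system requires r << 1"
        )
    reps = np.sqrt(edges[:-1] * np.maximum(edges[1:], 1e-300))
    rows = []
    labels: list[str] | None = None
    for r in reps:
        rho = 4.0 * model.N_ref * r
        vec = model.evaluate(rho)
        if normalization == "raw":
            labels = [l.to_string() for l in vec.basis.labels if l.family != "ONE"]
            keep = [k for k, l in enumerate(vec.basis.labels) if l.family != "ONE"]
            rows.append(vec.values[keep])
        else:
            labels, values = normalize_vector(vec, normalization)
            rows.append(values)
    return LDDecayCurve(
        bin_edges=edges,
        labels=labels,
        values=np.vstack(rows),
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# signed-D decay (single population, no migration)
# ---------------------------------------------------------------------------


def signed_d_decay(
    d0: float, nu: float, rho: float, T: float, dt: float | None = None
) -> float:
    """Crank-Nicolson decay of E[D] for one population: rate 1/nu + rho/2."""
    from .operators import signed_d_generator

    A = signed_d_generator([nu], rho)[0, 0]
    if dt is None:
        dt = default_dt(T)
    n_steps = max(1, int(math.ceil(T / dt)))
    h = T / n_steps
    step = (1 + h * A / 2.0) / (1 - h * A / 2.0)
    return d0 * step**n_steps


# ---------------------------------------------------------------------------
# YAML model description
# ---------------------------------------------------------------------------


def _convert_time(value: float, units: str, N_ref: float, generation_time: float) -> float:
    if units in ("2N", "scaled"):
        return float(value)
    if units == "generations":
        return float(value) / (2.0 * N_ref)
    if units == "years":
        return float(value) / (generation_time * 2.0 * N_ref)
    raise DemographyError(f"unknown time units {units!r}")


def model_from_dict(spec: dict) -> DemographicModel:
    """Build a model from a plain-dict (YAML/JSON) description.

    Keys: ``N_ref``, ``theta``, optional ``root``, ``time_units`` (``2N`` |
    ``generations`` | ``years``), ``generation_time`` (years, used only with
    ``time_units: years``), and ``events``: a list of single-key mappings
    (``epoch``, ``split``, ``admixture``, ``pulse``, ``marginalize``).
    Epoch migration rates are scaled (``mtilde``) unless
    ``rate_units: per_generation``.
    """
    N_ref = float(spec["N_ref"])
    units = spec.get("time_units", "2N")
    gen_time = float(spec.get("generation_time", 29.0))
    events: list[Event] = []
    for item in spec.get("events", []):
        if len(item) != 1:
            raise DemographyError(f"each event must have exactly one key: {item}")
        kind, body = next(iter(item.items()))
        if kind == "epoch":
            duration = _convert_time(body["duration"], units, N_ref, gen_time)
            sizes = body.get("sizes", 1.0)
            if isinstance(sizes, dict):
                sizes = {
                    k: tuple(v) if isinstance(v, (list, tuple)) else float(v)
                    for k, v in sizes.items()
                }
            migration: dict[tuple[str, str], float] = {}
            scale = 2.0 * N_ref if body.get("rate_units") == "per_generation" else 1.0
            for entry in body.get("migration", []):
                migration[(entry["source"], entry["dest"])] = float(entry["rate"]) * scale
            events.append(Epoch(duration=duration, sizes=sizes, migration=migration,
                                dt=body.get("dt")))
        elif kind == "split":
            events.append(Split(parent=body["parent"], children=tuple(body["children"])))
        elif kind == "admixture":
            events.append(
                Admixture(
                    source1=body["source1"],
                    source2=body["source2"],
                    fraction=float(body["fraction"]),
                    child=body["child"],
                    replace=bool(body.get("replace", False)),
                )
            )
        elif kind == "pulse":
            events.append(
                PulseInto(source=body["source"], dest=body["dest"],
                          fraction=float(body["fraction"]))
            )
        elif kind == "marginalize":
            events.append(Marginalize(population=body["population"]))
        else:
            raise DemographyError(f"unknown event kind {kind!r}")
    return DemographicModel(
        N_ref=N_ref,
        events=events,
        root=spec.get("root", "anc"),
        theta=float(spec.get("theta", 1e-3)),
    )


def model_from_yaml(path) -> DemographicModel:
    import yaml

    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
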