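"""Synthetic cohorts with plantable spatiotemporal structure.

This module emulates everything the pipeline consumes: a parcellation with
the eight functional systems, a structural connectome template (stochastic
block model with streamline-count weights), and two groups of subjects whose
regional activity is a union of *cascades* — transient activations that seed
at random regions and spread only along binarized structural edges.  Four
dials plant group differences that the downstream metrics should detect:

* ``cross_system_coupling`` (eta) scales propagation on between-system
  edges; higher eta yields more multi-system components and higher SD.
* ``drift_prob`` (rho): each cascade carries a "partner system" (initially
  the seed's own system) into which cross-system spread is *not* damped;
  with probability rho per frame the partner is redrawn among the other
  systems, so regions join components of shifting composition — higher STD.
* ``spread_prob`` controls per-edge propagation, hence component height.
* ``age_effect`` shrinks each subject's cascade extent cap linearly with
  age, planting a recoverable age effect on mean CC height.

Raster mode emits the binary activity directly; BOLD mode convolves it with
a fixed gamma-shaped kernel (unit peak at lag 0) and adds Gaussian noise, so
the point-process stage must recover the planted cells.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._core import (
    N_SYSTEMS,
    SYSTEMS,
    DimensionError,
    Parcellation,
    StructuralConnectome,
    ValidationError,
)

#: Gamma-difference impulse response sampled at the frame rate, normalized to
#: unit peak at lag 0 (causal, immediate peak, small late undershoot).
BOLD_KERNEL = np.array([1.0, 0.28, 0.08, 0.0, -0.04, -0.06, -0.04, -0.02, -0.01])

GroupParam = float | tuple[float, float]


def _per_group(value: GroupParam, group: str) -> float:
    """Resolve a scalar-or-(A,B)-pair parameter for one group."""
    if isinstance(value, (tuple, list)):
        return float(value[0] if group == "A" else value[1])
    return float(value)


def _check_prob(name: str, value: GroupParam) -> None:
    vals = value if isinstance(value, (tuple, list)) else (value,)
    for v in vals:
        if not 0.0 <= float(v) <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimParams:
    """Study-generation parameters.

    Defaults mirror the dimensioning of a school-age resting-state cohort:
    506 regions over 8 systems, 720 frames (6 min at TR 0.5 s), 42 + 45
    subjects aged 4.6-18 years.  ``event_rate``, ``spread_prob``,
    ``persist_prob``, ``cross_system_coupling`` and ``drift_prob`` accept a
    scalar or an (A, B) pair to plant group differences.
    """

    n_regions: int = 506
    regions_per_system: tuple[int, ...] | None = None
    p_in: float = 0.30
    p_out: float = 0.02
    n_subjects_a: int = 42
    n_subjects_b: int = 45
    n_frames: int = 720
    event_rate: GroupParam = 0.3
    spread_prob: GroupParam = 0.25
    cross_system_coupling: GroupParam = 0.1
    persist_prob: GroupParam = 0.5
    drift_prob: GroupParam = 0.1
    max_extent: int | None = None  # cascade cap on distinct regions; default N // 8
    age_low: float = 4.6
    age_high: float = 18.0
    age_ref: float | None = None  # cap shrink anchor; default mid-range
    age_effect: float = 0.0  # fractional cap shrink per year above age_ref
    ages: dict[str, list[float]] | None = None  # explicit per-group ages
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < N_SYSTEMS:
            raise DimensionError("need at least one region per system")
        for nm in ("n_subjects_a", "n_subjects_b", "n_frames"):
            if getattr(self, nm) <= 0:
                raise ValidationError(f"{nm} must be positive")
        for nm in (
            "p_in",
            "p_out",
            "spread_prob",
            "cross_system_coupling",
            "persist_prob",
            "drift_prob",
        ):
            _check_prob(nm, getattr(self, nm))
        er = self.event_rate if isinstance(self.event_rate, (tuple, list)) else (self.event_rate,)
        if any(float(v) < 0 for v in er):
            raise ValidationError("event_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def extent_cap_base(self) -> int:
        return self.max_extent if self.max_extent is not None else max(4, self.n_regions // 8)

    @property
    def age_anchor(self) -> float:
        return self.age_ref if self.age_ref is not None else 0.5 * (self.age_low + self.age_high)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    age: float
    data: np.ndarray  # N x T; binary in raster mode, real in bold mode
    mode: str


@dataclass(frozen=True)
class Cohort:
    subjects: list[Subject]
    mode: str
    cascade_log: list[dict] | None = None


def generate_parcellation(
    n_regions: int,
    regions_per_system: tuple[int, ...] | None = None,
    seed: int = 0,
) -> Parcellation:
    """Random region-to-system assignment with fixed per-system counts.

    With ``regions_per_system=None`` the regions are split as evenly as
    possible over the 8 systems.  System membership is shuffled over region
    ids (regions of one system are not contiguous), deterministically for a
    fixed seed.
    """
    if regions_per_system is None:
        base, extra = divmod(n_regions, N_SYSTEMS)
        regions_per_system = tuple(base + (1 if k < extra else 0) for k in range(N_SYSTEMS))
    if len(regions_per_system) != N_SYSTEMS:
        raise DimensionError(f"regions_per_system needs {N_SYSTEMS} entries")
    if sum(regions_per_system) != n_regions:
        raise DimensionError(
            f"regions_per_system sums to {sum(regions_per_system)}, expected {n_regions}"
        )
    rng = np.random.default_rng(seed)
    systems = np.repeat(np.array(SYSTEMS, dtype=object), regions_per_system)
    rng.shuffle(systems)
    names = np.array([f"R{i:04d}" for i in range(n_regions)], dtype=object)
    return Parcellation(region_names=names, systems=systems)


def generate_structural_connectome(
    labels: Parcellation,
    p_in: float = 0.30,
    p_out: float = 0.05,
    seed: int = 0,
) -> StructuralConnectome:
    """Stochastic-block-model template with streamline-count weights.

    Region pairs within a functional system connect with probability
    ``p_in``, pairs across systems with ``p_out``; present edges get a
    positive integer weight (1 + Poisson) mimicking streamline counts.
    """
    for name, p in (("p_in", p_in), ("p_out", p_out)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {p}")
    if p_out > p_in:
        raise ValidationError("expected p_out <= p_in (assortative template)")
    rng = np.random.default_rng(seed)
    n = labels.n_regions
    same = labels.system_idx[:, None] == labels.system_idx[None, :]
    probs = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((n, n)) < probs, k=1)
    weights = np.where(upper, rng.poisson(15.0, size=(n, n)) + 1.0, 0.0)
    weights = weights + weights.T
    return StructuralConnectome(weights=weights)


class _Cascade:
    __slots__ = ("active", "seen", "home", "partner", "nodes")

    def __init__(self, seed_region: int, home: int, log_nodes: bool):
        self.active = np.array([seed_region], dtype=np.int64)
        self.seen = {int(seed_region)}
        self.home = home
        self.partner = home
        self.nodes: list[tuple[int, int]] | None = [] if log_nodes else None


def _simulate_raster(
    rng: np.random.Generator,
    neighbors: list[np.ndarray],
    system_idx: np.ndarray,
    n_frames: int,
    event_rate: float,
    spread_prob: float,
    eta: float,
    persist_prob: float,
    drift_prob: float,
    extent_cap: int,
    log_cascades: bool,
) -> tuple[np.ndarray, list[dict]]:
    n_regions = system_idx.size
    raster = np.zeros((n_regions, n_frames), dtype=bool)
    cascades: list[_Cascade] = []
    finished: list[dict] = []

    for t in range(n_frames):
        for _ in range(rng.poisson(event_rate)):
            r = int(rng.integers(n_regions))
            cascades.append(_Cascade(r, int(system_idx[r]), log_cascades))

        still_alive: list[_Cascade] = []
        for casc in cascades:
            raster[casc.active, t] = True
            if casc.nodes is not None:
                casc.nodes.extend((int(r), t) for r in casc.active)

            if t == n_frames - 1:
                continue
            # survival of currently active regions
            keep = casc.active[rng.random(casc.active.size) < persist_prob]
            # propagation along structural edges
            new: set[int] = set()
            budget = extent_cap - len(casc.seen)
            if budget > 0 and spread_prob > 0:
                for r in casc.active:
                    nb = neighbors[r]
                    if nb.size == 0:
                        continue
                    p = np.full(nb.size, spread_prob)
                    cross = system_idx[nb] != system_idx[r]
                    not_partner = system_idx[nb] != casc.partner
                    p[cross & not_partner] *= eta
                    hits = nb[rng.random(nb.size) < p]
                    for j in hits:
                        j = int(j)
                        if j in casc.seen or j in new:
                            continue
                        new.add(j)
                        if len(new) >= budget:
                            break
                    if len(new) >= budget:
                        break
            if rng.random() < drift_prob:
                others = [s for s in range(N_SYSTEMS) if s != casc.home]
                casc.partner = int(others[rng.integers(len(others))])
            nxt = np.union1d(keep, np.array(sorted(new), dtype=np.int64))
            if nxt.size == 0:
                if casc.nodes is not None:
                    finished.append({"nodes": casc.nodes, "home": casc.home})
                continue
            casc.seen.update(int(j) for j in new)
            casc.active = nxt
            still_alive.append(casc)
        if t < n_frames - 1:
            cascades = still_alive

    if log_cascades:
        finished.extend(
            {"nodes": c.nodes, "home": c.home} for c in cascades if c.nodes is not None
        )
    return raster, finished


def raster_to_bold(
    raster: np.ndarray, rng: np.random.Generator, noise_sd: float
) -> np.ndarray:
    """Convolve a binary raster with the fixed kernel and add Gaussian noise."""
    n_frames = raster.shape[1]
    signal = np.apply_along_axis(
        lambda row: np.convolve(row, BOLD_KERNEL)[:n_frames], 1, raster.astype(float)
    )
    return signal + rng.normal(0.0, noise_sd, size=signal.shape)


def generate_cohort(
    params: SimParams,
    labels: Parcellation,
    sc: StructuralConnectome,
    mode: str = "raster",
    log_cascades: bool = False,
) -> Cohort:
    """Two-group cohort of regional activity; deterministic for a fixed seed.

    Raster mode emits binary N x T matrices whose active cells are unions of
    cascades that only ever spread along binarized structural edges.  BOLD
    mode additionally convolves with :data:`BOLD_KERNEL` and adds
    ``N(0, noise_sd)`` noise.
    """
    if mode not in ("raster", "bold"):
        raise ValidationError(f"mode must be 'raster' or 'bold', got {mode!r}")
    if labels.n_regions != params.n_regions or sc.n_regions != params.n_regions:
        raise DimensionError("labels/structural matrix inconsistent with params")

    adj = sc.binarized()
    neighbors = [np.flatnonzero(adj[i]) for i in range(params.n_regions)]

    subjects: list[Subject] = []
    all_logs: list[dict] = []
    roster = [("A", k, params.n_subjects_a) for k in range(params.n_subjects_a)] + [
        ("B", k, params.n_subjects_b) for k in range(params.n_subjects_b)
    ]
    # independent cascade/noise streams per subject so the underlying raster
    # does not depend on the output mode or on other subjects
    children = np.random.SeedSequence(params.seed).spawn(len(roster))
    for (group, k, _n), child in zip(roster, children):
        casc_ss, noise_ss = child.spawn(2)
        rng = np.random.default_rng(casc_ss)
        sid = f"{group}{k + 1:03d}"
        if params.ages is not None:
            age = float(params.ages[group][k])
        else:
            age = float(rng.uniform(params.age_low, params.age_high))
        shrink = 1.0 - params.age_effect * (age - params.age_anchor)
        cap = max(1, int(round(params.extent_cap_base * max(shrink, 0.05))))
        raster, log = _simulate_raster(
            rng,
            neighbors,
            labels.system_idx,
            params.n_frames,
            event_rate=_per_group(params.event_rate, group),
            spread_prob=_per_group(params.spread_prob, group),
            eta=_per_group(params.cross_system_coupling, group),
            persist_prob=_per_group(params.persist_prob, group),
            drift_prob=_per_group(params.drift_prob, group),
            extent_cap=cap,
            log_cascades=log_cascades,
        )
        if mode == "bold":
            data = raster_to_bold(raster, np.random.default_rng(noise_ss), params.noise_sd)
        else:
            data = raster
        subjects.append(Subject(sid, group, age, data, mode))
        if log_cascades:
            for entry in log:
                entry["subject_id"] = sid
            all_logs.extend(log)

    return Cohort(subjects=subjects, mode=mode, cascade_log=all_logs if log_cascades else None)


def params_hash(params: SimParams) -> str:
    blob = yaml.safe_dump(asdict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_cohort(
    outdir: str | Path,
    cohort: Cohort,
    labels: Parcellation,
    sc: StructuralConnectome,
    params: SimParams,
) -> Path:
    """Write a cohort as the plain-text study layout the pipeline reads.

    Layout: ``labels.tsv`` (region_id, region_name, system), ``sc.tsv``
    (N x N), ``manifest.csv`` (subject_id, group, age, path), one
    ``<subject>.tsv`` activity matrix per subject (rows = regions), and a
    ``params.yaml`` snapshot recording every parameter and the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import io as stio

    stio.write_labels(outdir / "labels.tsv", labels)
    stio.write_matrix_tsv(outdir / "sc.tsv", sc.weights)
    rows = []
    for s in cohort.subjects:
        rel = f"{s.subject_id}.tsv"
        fmt = "%d" if cohort.mode == "raster" else "%.6f"
        stio.write_matrix_tsv(outdir / rel, s.data.astype(float), fmt=fmt)
        rows.append({"subject_id": s.subject_id, "group": s.group, "age": s.age, "path": rel})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    snapshot = asdict(params)
    snapshot["params_hash"] = params_hash(params)
    snapshot["mode"] = cohort.mode
    (outdir / "params.yaml").write_text(yaml.safe_dump(snapshot, sort_keys=True))
    return outdir
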