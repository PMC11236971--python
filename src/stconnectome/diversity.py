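"""System embeddings and the two group-level diversity metrics.

Each connected component (CC) is embedded as an 8-long vector of activation
mass per functional system (mass[f] = sum of the CC's spatial activation
vector over the regions labeled f).  Two pool-level metrics follow:

* **System diversity (SD)** — per-CC normalized entropy of the system mass
  distribution (natural log, divided by ln 8), averaged over the pool.
  SD = 0 when every CC is confined to a single system; SD = 1 when mass is
  spread evenly over all 8 systems.  Higher SD means more cross-system
  integration.
* **Spatiotemporal diversity (STD)** — for each region participating in at
  least two pooled CCs, one minus the mean pairwise cosine similarity of the
  unit embeddings of those CCs, averaged over qualifying regions.  Lower STD
  means a region keeps a stable system composition over time.

Both metrics are group-level: they need a pool of CCs (all subjects of a
group concatenated) and are not defined per subject.  At the functional
system scale, a CC enters system f's sub-pool when at least 20% of its
involved regions are labeled f (the maximal-share system is always kept, so
no CC is orphaned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._core import N_SYSTEMS, SYSTEMS, InsufficientDataError, Parcellation, ValidationError
from .stgraph import ConnectedComponent

#: Valid metric scales: whole pool, or one per functional system.
SCALES = ("global",) + SYSTEMS


@dataclass(frozen=True)
class DiversityValue:
    scale: str
    metric: str
    value: float
    n_cc_used: int
    n_regions_used: int


def embed(cc: ConnectedComponent, parc: Parcellation) -> np.ndarray:
    """8-long activation-mass vector of a CC; conserves sum(mass) = CC size."""
    if parc.n_regions != cc.n_regions_total:
        raise ValidationError(
            f"parcellation has {parc.n_regions} regions but CC was built on "
            f"{cc.n_regions_total}"
        )
    mass = np.bincount(
        parc.system_idx[cc.regions], weights=cc.frame_counts, minlength=N_SYSTEMS
    )
    return mass


def unit_embedding(mass: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(mass)
    if norm == 0:
        raise ValidationError("cannot normalize an all-zero embedding")
    return mass / norm


def normalized_entropy(mass: np.ndarray) -> float:
    """Shannon entropy of mass/sum(mass) in nats, normalized by ln 8 to [0,1]."""
    total = mass.sum()
    if total <= 0:
        raise ValidationError("embedding has no mass")
    p = mass[mass > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(N_SYSTEMS))


def attribute_systems(
    cc: ConnectedComponent, parc: Parcellation, frac: float = 0.20
) -> set[str]:
    """Functional systems a CC is attributed to at the system scale.

    A CC belongs to every system holding at least ``frac`` of its involved
    regions (distinct regions with x_i > 0).  The system with the maximal
    share is always included, so every CC is attributed somewhere.
    """
    shares = _region_shares(cc, parc)
    keep = shares >= frac
    keep[int(np.argmax(shares))] = True
    return {SYSTEMS[f] for f in np.flatnonzero(keep)}


def _region_shares(cc: ConnectedComponent, parc: Parcellation) -> np.ndarray:
    counts = np.bincount(parc.system_idx[cc.regions], minlength=N_SYSTEMS)
    return counts / cc.n_regions_involved


class CCPool:
    """Concatenated CCs of one group, with precomputed embedding arrays.

    Attributes
    ----------
    entropies : (n_cc,) normalized per-CC entropies
    unit_emb : (n_cc, 8) L2-normalized system embeddings
    region_shares : (n_cc, 8) share of involved regions per system
    subjects : (n_cc,) owning subject id per CC
    incidence : (N, n_cc) sparse boolean region-in-CC matrix
    """

    def __init__(
        self,
        components: list[ConnectedComponent],
        parc: Parcellation,
        subject_ids: list[str] | None = None,
    ):
        self.parc = parc
        self.components = list(components)
        n = len(self.components)
        if subject_ids is None:
            subject_ids = [c.subject_id for c in self.components]
        if len(subject_ids) != n:
            raise ValidationError("one subject id per component required")
        self.subjects = np.asarray(subject_ids, dtype=object)

        mass = np.zeros((n, N_SYSTEMS))
        shares = np.zeros((n, N_SYSTEMS))
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        for k, cc in enumerate(self.components):
            mass[k] = embed(cc, parc)
            shares[k] = _region_shares(cc, parc)
            rows.append(cc.regions)
            cols.append(np.full(cc.regions.size, k, dtype=np.int64))
        self.mass = mass
        norms = np.linalg.norm(mass, axis=1, keepdims=True)
        self.unit_emb = np.divide(
            mass, norms, out=np.zeros_like(mass), where=norms > 0
        )
        self.entropies = np.array(
            [normalized_entropy(m) for m in mass]
        ) if n else np.empty(0)
        self.region_shares = shares
        r = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
        c = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
        self.incidence = sparse.coo_matrix(
            (np.ones(r.size), (r, c)), shape=(parc.n_regions, n)
        ).tocsr()

    @property
    def n_cc(self) -> int:
        return len(self.components)

    def attribution_mask(self, frac: float = 0.20) -> np.ndarray:
        """(n_cc, 8) boolean: CC k attributed to system f (20% rule + argmax)."""
        if self.n_cc == 0:
            return np.zeros((0, N_SYSTEMS), dtype=bool)
        keep = self.region_shares >= frac
        keep[np.arange(self.n_cc), np.argmax(self.region_shares, axis=1)] = True
        return keep

    def subset(self, mask: np.ndarray) -> "CCPool":
        """Sub-pool selecting CCs where ``mask`` is True (boolean or index array)."""
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        comps = [self.components[k] for k in idx]
        sub = CCPool.__new__(CCPool)
        sub.parc = self.parc
        sub.components = comps
        sub.subjects = self.subjects[idx]
        sub.mass = self.mass[idx]
        sub.unit_emb = self.unit_emb[idx]
        sub.entropies = self.entropies[idx]
        sub.region_shares = self.region_shares[idx]
        sub.incidence = self.incidence[:, idx].tocsr()
        return sub

    def restrict_to_system(self, system: str, frac: float = 0.20) -> "CCPool":
        if system not in SYSTEMS:
            raise ValidationError(f"unknown system {system!r}")
        mask = self.attribution_mask(frac)[:, SYSTEMS.index(system)]
        return self.subset(mask)


def system_diversity(pool: CCPool, variant: str = "mean_cc") -> DiversityValue:
    """Group SD of a pool.

    ``variant='mean_cc'`` (default) averages per-CC normalized entropies;
    ``'pooled_hist'`` takes the entropy of the pooled system histogram.
    """
    if pool.n_cc == 0:
        raise InsufficientDataError("SD needs a nonempty pool of components")
    if variant == "mean_cc":
        value = float(pool.entropies.mean())
    elif variant == "pooled_hist":
        value = normalized_entropy(pool.mass.sum(axis=0))
    else:
        raise ValidationError(f"unknown SD variant {variant!r}")
    return DiversityValue("global", "SD", value, pool.n_cc, 0)


def _region_pair_stats(pool: CCPool) -> tuple[np.ndarray, np.ndarray]:
    """Per-region sum of unit embeddings and CC counts over the pool."""
    s = pool.incidence @ pool.unit_emb  # (N, 8)
    n = np.asarray(pool.incidence.sum(axis=1)).ravel()
    return s, n


def std_from_stats(s: np.ndarray, n: np.ndarray) -> tuple[float, int]:
    """STD from per-region embedding sums and counts (closed form).

    For a region with n unit vectors summing to s, the mean pairwise cosine
    is (||s||^2 - n) / (n (n - 1)); STD is one minus that, averaged over
    regions with n >= 2.
    """
    qual = n >= 2
    n_used = int(qual.sum())
    if n_used == 0:
        raise InsufficientDataError(
            "STD needs at least one region participating in >= 2 components"
        )
    nq = n[qual]
    normsq = (s[qual] ** 2).sum(axis=1)
    mean_cos = (normsq - nq) / (nq * (nq - 1))
    value = float(np.clip(1.0 - mean_cos, 0.0, 1.0).mean())
    return value, n_used


def spatiotemporal_diversity(
    pool: CCPool, variant: str = "region_pairs"
) -> DiversityValue:
    """Group STD of a pool.

    ``variant='region_pairs'`` (default) averages, over regions in >= 2 CCs,
    one minus the mean pairwise cosine between the embeddings of the CCs the
    region participates in; ``'all_pairs'`` uses every CC pair of the pool.
    """
    if variant == "region_pairs":
        s, n = _region_pair_stats(pool)
        value, n_regions = std_from_stats(s, n)
        return DiversityValue("global", "STD", value, pool.n_cc, n_regions)
    if variant == "all_pairs":
        if pool.n_cc < 2:
            raise InsufficientDataError("all-pairs STD needs >= 2 components")
        s = pool.unit_emb.sum(axis=0)
        n = pool.n_cc
        mean_cos = ((s**2).sum() - n) / (n * (n - 1))
        value = float(np.clip(1.0 - mean_cos, 0.0, 1.0))
        return DiversityValue("global", "STD", value, pool.n_cc, 0)
    raise ValidationError(f"unknown STD variant {variant!r}")


def scale_metrics(
    pool: CCPool,
    frac: float = 0.20,
    sd_variant: str = "mean_cc",
    std_variant: str = "region_pairs",
) -> list[DiversityValue]:
    """SD and STD at the global scale and per functional system.

    Sub-pools too small for a metric yield NaN values with zero counts
    (flagged missing), never an exception.
    """
    if pool.n_cc == 0:
        raise InsufficientDataError("scale metrics need a nonempty pool")
    out: list[DiversityValue] = []
    att = pool.attribution_mask(frac)
    for scale in SCALES:
        sub = pool if scale == "global" else pool.subset(att[:, SYSTEMS.index(scale)])
        for metric, fn in (
            ("SD", lambda p: system_diversity(p, sd_variant)),
            ("STD", lambda p: spatiotemporal_diversity(p, std_variant)),
        ):
            try:
                dv = fn(sub)
                out.append(
                    DiversityValue(scale, metric, dv.value, dv.n_cc_used, dv.n_regions_used)
                )
            except InsufficientDataError:
                out.append(DiversityValue(scale, metric, float("nan"), 0, 0))
    return out
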