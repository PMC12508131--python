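"""Clonal evolution from paired diagnosis/relapse VAFs.

Variants are clustered in diagnosis-vs-relapse VAF space with a
two-dimensional binomial mixture model fitted by expectation-maximization
on the raw (alt, depth) pairs; the number of clusters is chosen by the
Bayesian information criterion.  Cluster centroids then drive the seeding
classification - relapse seeded by multiple diagnostic clones, or by a
single sweeping clone that was or was not detected at diagnosis - and
clone-fraction trajectories across serial samples in the layout fish-plot
tools consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

DETECTION_LIMIT_VAF = 0.002
PRESENCE_VAF = 0.05
NESTING_TOL = 0.02

_P_FLOOR = 1e-7


@dataclass
class CloneCluster:
    """A variant cluster with joint diagnosis/relapse VAF centroids."""

    id: str
    members: list[str]
    centroid_diag: float
    centroid_relapse: float
    detected_at_diagnosis: bool

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.id} has no members")
        for c in (self.centroid_diag, self.centroid_relapse):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"cluster {self.id}: centroid {c} outside [0,1]")


@dataclass(frozen=True)
class SeedingPattern:
    value: str  # multiple_clones | sweep_detected | sweep_not_detected
    branching: bool


@dataclass
class ClonalTrajectory:
    clone: str
    parent: str | None
    points: list[tuple[int, float]]  # (day, cell fraction)
    interpolated_days: tuple[int, ...] = ()
    nesting_violation: bool = False


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    p_diag: np.ndarray
    p_relapse: np.ndarray
    log_likelihood: float
    bic: float
    assignments: np.ndarray
    responsibilities: np.ndarray
    loglik_trace: list[float]
    trivial: bool = False


def _binom_loglik_terms(alt: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """log C(depth, alt) per observation (constant across clusters)."""
    return gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)


def _em_once(
    a1, d1, a2, d2, k: int, rng: np.random.Generator, max_iter: int = 300,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    n = a1.size
    v1 = np.where(d1 > 0, a1 / np.maximum(d1, 1), 0.0)
    v2 = np.where(d2 > 0, a2 / np.maximum(d2, 1), 0.0)
    pts = np.column_stack([v1, v2])
    # k-means++ style seeding on the VAF points
    centers = [pts[rng.integers(n)]]
    for _ in range(1, k):
        dist = np.min(
            [np.sum((pts - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = dist.sum()
        if total <= 0:
            centers.append(pts[rng.integers(n)])
        else:
            centers.append(pts[rng.choice(n, p=dist / total)])
    centers = np.asarray(centers)
    p1 = np.clip(centers[:, 0], _P_FLOOR, 1 - _P_FLOOR)
    p2 = np.clip(centers[:, 1], _P_FLOOR, 1 - _P_FLOOR)
    w = np.full(k, 1.0 / k)
    const = float(
        np.sum(_binom_loglik_terms(a1, d1) + _binom_loglik_terms(a2, d2))
    )
    r1 = d1 - a1
    r2 = d2 - a2
    prev = -np.inf
    trace: list[float] = []

    def e_step(w, p1, p2):
        log_joint = (
            a1[:, None] * np.log(p1)
            + r1[:, None] * np.log1p(-p1)
            + a2[:, None] * np.log(p2)
            + r2[:, None] * np.log1p(-p2)
            + np.log(np.maximum(w, 1e-300))
        )
        m = log_joint.max(axis=1)
        ex = np.exp(log_joint - m[:, None])
        norm = ex.sum(axis=1)
        loglik = float(np.sum(m + np.log(norm))) + const
        resp = ex / norm[:, None]
        return loglik, resp

    resp = None
    for _ in range(max_iter):
        loglik, resp = e_step(w, p1, p2)
        trace.append(loglik)
        # M step
        w = resp.sum(axis=0) / n
        p1 = np.clip(
            a1 @ resp / np.maximum(d1 @ resp, 1e-12), _P_FLOOR, 1 - _P_FLOOR
        )
        p2 = np.clip(
            a2 @ resp / np.maximum(d2 @ resp, 1e-12), _P_FLOOR, 1 - _P_FLOOR
        )
        if loglik - prev < tol * max(1.0, abs(loglik)) and len(trace) > 1:
            break
        prev = loglik
    # final E step: assignments at the converged parameters
    loglik, resp = e_step(w, p1, p2)
    trace.append(loglik)
    return loglik, w, p1, p2, resp, trace


def fit_binomial_mixture(
    a1, d1, a2, d2, k: int, seed: int = 0, restarts: int = 10,
) -> MixtureFit:
    """Fit a k-component 2D binomial mixture by EM with seeded restarts.

    The EM log-likelihood is asserted non-decreasing on every run.  For
    k = 1 the solution is the closed-form pooled binomial estimate.
    """
    a1 = np.asarray(a1, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = a1.size
    rng = np.random.default_rng(seed)
    best = None
    n_restarts = 1 if k == 1 else restarts
    for _ in range(n_restarts):
        loglik, w, p1, p2, resp, trace = _em_once(a1, d1, a2, d2, k, rng)
        diffs = np.diff(trace)
        if np.any(diffs < -1e-6 * np.maximum(1.0, np.abs(trace[:-1]))):
            raise AssertionError("EM log-likelihood decreased")
        if best is None or loglik > best[0]:
            best = (loglik, w, p1, p2, resp, trace)
    loglik, w, p1, p2, resp, trace = best
    n_params = 3 * k - 1  # k-1 weights + 2k binomial parameters
    bic = -2.0 * loglik + n_params * np.log(n)
    return MixtureFit(
        k=k, weights=w, p_diag=p1, p_relapse=p2, log_likelihood=loglik,
        bic=bic, assignments=resp.argmax(axis=1), responsibilities=resp,
        loglik_trace=trace,
    )


def cluster_vafs(
    paired_obs,
    min_depth: int = 10,
    max_k: int = 6,
    seed: int = 0,
    restarts: int = 10,
    detection_limit: float = DETECTION_LIMIT_VAF,
) -> list[CloneCluster]:
    """Cluster variants in diagnosis-vs-relapse VAF space.

    ``paired_obs`` is an iterable of (variant_id, diag Observation,
    relapse Observation); every variant must pass the depth gate in both
    samples (VAFs are assumed CCF-corrected upstream when copy number is
    aberrant).  Binomial mixtures for k = 1..max_k are fitted by EM and the
    Bayesian information criterion picks k.  Fewer than 3 variants yield a
    single trivial cluster flagged as such.
    """
    ids, a1, d1, a2, d2 = [], [], [], [], []
    for vid, od, orl in paired_obs:
        if od.depth < min_depth or orl.depth < min_depth:
            raise ValueError(
                f"{vid}: observation below the minimum depth {min_depth}"
            )
        ids.append(vid)
        a1.append(od.alt_reads)
        d1.append(od.depth)
        a2.append(orl.alt_reads)
        d2.append(orl.depth)
    if not ids:
        raise ValueError("no variants to cluster")
    a1 = np.asarray(a1, float)
    d1 = np.asarray(d1, float)
    a2 = np.asarray(a2, float)
    d2 = np.asarray(d2, float)
    if len(ids) < 3:
        c1 = float(a1.sum() / d1.sum())
        c2 = float(a2.sum() / d2.sum())
        return [
            CloneCluster(
                id="trivial", members=list(ids), centroid_diag=c1,
                centroid_relapse=c2,
                detected_at_diagnosis=c1 >= detection_limit,
            )
        ]
    fits = [
        fit_binomial_mixture(a1, d1, a2, d2, k, seed=seed + k, restarts=restarts)
        for k in range(1, max_k + 1)
    ]
    fit = min(fits, key=lambda f: f.bic)
    clusters = []
    for j in range(fit.k):
        members = [ids[i] for i in np.flatnonzero(fit.assignments == j)]
        if not members:
            continue
        cd = float(fit.p_diag[j])
        cr = float(fit.p_relapse[j])
        clusters.append(
            CloneCluster(
                id=f"clone{len(clusters) + 1}",
                members=members,
                centroid_diag=cd,
                centroid_relapse=cr,
                detected_at_diagnosis=cd >= detection_limit,
            )
        )
    # stable ordering: by descending diagnostic centroid
    clusters.sort(key=lambda c: (-c.centroid_diag, -c.centroid_relapse))
    for i, c in enumerate(clusters):
        c.id = f"clone{i + 1}"
    return clusters


def classify_seeding(
    clusters: list[CloneCluster],
    detection_limit: float = DETECTION_LIMIT_VAF,
    presence_threshold: float = PRESENCE_VAF,
) -> SeedingPattern:
    """Diagnosis-to-relapse seeding pattern from cluster centroids.

    Relapse clusters are those clonally present at relapse (centroid above
    ``presence_threshold``).  With >= 2 of them detected at diagnosis the
    relapse was seeded by multiple diagnostic clones; with exactly one, by a
    single sweeping clone detected at diagnosis; with none, by a clone below
    the diagnostic detection limit.  Branching evolution is the loss at
    relapse of a cluster present at diagnosis.
    """
    relapse_clusters = [
        c for c in clusters if c.centroid_relapse > presence_threshold
    ]
    if not relapse_clusters:
        raise ValueError("no relapse sample signal among the clusters")
    detected = [
        c for c in relapse_clusters if c.centroid_diag >= detection_limit
    ]
    if len(detected) >= 2:
        value = "multiple_clones"
    elif len(detected) == 1:
        value = "sweep_detected"
    else:
        value = "sweep_not_detected"
    branching = any(
        c.centroid_diag > presence_threshold and c.centroid_relapse < detection_limit
        for c in clusters
    )
    return SeedingPattern(value=value, branching=branching)


def assign_parents(
    fractions: dict[str, dict[int, float]], parent_tol: float = 0.1
) -> dict[str, str | None]:
    """Containment heuristic: the parent of a clone is the smallest clone
    whose fraction dominates it at every shared timepoint.

    ``parent_tol`` is deliberately coarser than the nesting-violation
    tolerance: noisy containment still assigns a parent, and residual
    excesses beyond NESTING_TOL are then flagged downstream rather than
    orphaning the clone.
    """
    parents: dict[str, str | None] = {}
    sizes = {c: sum(f.values()) for c, f in fractions.items()}
    for c, f in fractions.items():
        candidates = []
        for other, g in fractions.items():
            if other == c:
                continue
            if (
                all(g.get(d, 0.0) >= f[d] - parent_tol for d in f)
                and sizes[other] >= sizes[c]
            ):
                candidates.append(other)
        parents[c] = min(candidates, key=lambda o: sizes[o]) if candidates else None
    return parents


def track_trajectories(
    serial_vafs: dict[str, dict[int, float | None]],
    clusters: list[CloneCluster],
    tol: float = NESTING_TOL,
) -> list[ClonalTrajectory]:
    """Clone-fraction trajectories across serial samples.

    ``serial_vafs`` maps variant id -> {day: CCF-corrected VAF or None when
    the observation failed the depth gate}.  A clone's fraction at a day is
    twice the mean VAF of its member variants (heterozygous diploid cell
    fraction), capped at the parent fraction; a raw excess beyond ``tol``
    raises the trajectory's violation flag instead of being silently
    clipped.  Days with no usable member observation are linearly
    interpolated and flagged.
    """
    days = sorted({d for v in serial_vafs.values() for d in v})
    if len(days) < 2:
        raise ValueError("trajectory tracking needs >= 2 timepoints")
    raw: dict[str, dict[int, float]] = {}
    gaps: dict[str, tuple[int, ...]] = {}
    for cl in clusters:
        vals_by_day: dict[int, float] = {}
        missing = []
        for d in days:
            vv = [
                serial_vafs[m][d]
                for m in cl.members
                if m in serial_vafs and serial_vafs[m].get(d) is not None
            ]
            if vv:
                vals_by_day[d] = min(2.0 * float(np.mean(vv)), 1.0)
            else:
                missing.append(d)
        if not vals_by_day:
            raise ValueError(f"cluster {cl.id} has no usable observations")
        known_d = np.array(sorted(vals_by_day))
        known_f = np.array([vals_by_day[d] for d in known_d])
        filled = np.interp(np.asarray(days, float), known_d.astype(float), known_f)
        raw[cl.id] = {d: float(f) for d, f in zip(days, filled)}
        gaps[cl.id] = tuple(missing)
    parents = assign_parents(raw)
    out = []
    for cl in clusters:
        f = raw[cl.id]
        parent = parents[cl.id]
        violation = False
        points = []
        for d in days:
            val = f[d]
            if parent is not None:
                pf = raw[parent][d]
                if val > pf + tol:
                    violation = True
                val = min(val, pf)
            points.append((d, val))
        out.append(
            ClonalTrajectory(
                clone=cl.id,
                parent=parent,
                points=points,
                interpolated_days=gaps[cl.id],
                nesting_violation=violation,
            )
        )
    return out


def trajectory_table(trajectories: list[ClonalTrajectory]):
    """Fish-plot convention table: one row per clone per timepoint."""
    import pandas as pd

    rows = []
    for t in trajectories:
        for day, frac in t.points:
            rows.append(
                {
                    "clone": t.clone,
                    "parent": t.parent if t.parent is not None else "",
                    "day": day,
                    "fraction": frac,
                    "interpolated": day in t.interpolated_days,
                    "nesting_violation": t.nesting_violation,
                }
            )
    return pd.DataFrame(rows)
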