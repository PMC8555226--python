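"""Projection of observed degree distributions onto randomized networks.

Two regimes:

* **Scale-free target** (e.g. a preferential-attachment null): each source
  node's degree is transferred to a node of equal degree in the target
  network; degrees below the target's minimum are floored at K_min(target),
  and degrees absent from the target are mapped to the nearest present
  value.
* **Normal-degree target** (ER / WS nulls, whose degree spread is far
  narrower than a scale-free network's): random node sets of the source
  sizes are selected so that their mean and standard deviation of degree
  satisfy a log-scaling of the source distribution:

      K_mean(random) ~ K_min(r) + (K_max(r) - K_min(r)) * log(K_mean(source set)) / log(K_max(source network))
      sd(random)     ~ (K_max(r) - K_min(r)) * sd(log10 of source set degrees)

  Selection is by seeded proposal sampling (truncated normal in degree
  space with adaptive rescaling) accepted when achieved mean and s.d. are
  both within a relative tolerance (default 5%).  Shapiro-Wilk normality of
  each selected set is reported, not enforced.

Logs are base 10; the mean rule's ratio of logs is base-invariant, the s.d.
rule is base-dependent and follows the log10 plotting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats


@dataclass
class ProjectionSpec:
    tolerance: float = 0.05
    max_tries: int = 10_000
    seed: int | None = None
    k_max_source: float | None = None  # max degree of the source network


@dataclass
class ProjectionResult:
    nodes: list
    degrees: np.ndarray
    achieved_mean: float
    achieved_sd: float
    target_mean: float | None = None
    target_sd: float | None = None
    shapiro_p: float | None = None
    tries: int = 1
    meta: dict = field(default_factory=dict)


def _degree_index(graph: nx.Graph):
    by_degree: dict[int, list] = {}
    for v, d in graph.degree():
        by_degree.setdefault(int(d), []).append(v)
    if not by_degree:
        raise ValueError("target network is empty")
    return by_degree, np.array(sorted(by_degree), dtype=int)


def project_onto_scalefree(
    source_degrees, target: nx.Graph, seed: int | None = None
) -> ProjectionResult:
    """Map source degrees onto equal (or nearest) degree nodes of the target.

    Degrees below K_min(target) are floored at K_min(target).  One node is
    drawn (seeded) among the candidates of the mapped degree, without
    replacement while candidates remain.
    """
    rng = np.random.default_rng(seed)
    by_degree, present = _degree_index(target)
    available = {d: list(vs) for d, vs in by_degree.items()}
    k_min = int(present[0])
    chosen_nodes, chosen_degrees = [], []
    for d in source_degrees:
        d = max(int(d), k_min)
        candidates = [k for k in present if available.get(int(k))]
        if not candidates:
            raise ValueError("target network exhausted during projection")
        mapped = int(min(candidates, key=lambda k: (abs(int(k) - d), k)))
        pool = available[mapped]
        node = pool.pop(int(rng.integers(len(pool))))
        chosen_nodes.append(node)
        chosen_degrees.append(mapped)
    degrees = np.asarray(chosen_degrees, dtype=float)
    return ProjectionResult(
        nodes=chosen_nodes,
        degrees=degrees,
        achieved_mean=float(degrees.mean()),
        achieved_sd=float(degrees.std(ddof=1)) if degrees.size > 1 else 0.0,
        meta={"k_min_target": k_min},
    )


def matched_set_targets(
    source_degrees, target: nx.Graph, k_max_source: float
) -> tuple[float, float]:
    """Target mean and s.d. of degree for a criteria-matched random set."""
    src = np.asarray(list(source_degrees), dtype=float)
    if (src <= 0).any():
        raise ValueError("source degrees must be positive")
    degrees = np.array([d for _, d in target.degree()], dtype=float)
    k_min_r, k_max_r = degrees.min(), degrees.max()
    span = k_max_r - k_min_r
    target_mean = k_min_r + span * np.log10(src.mean()) / np.log10(k_max_source)
    target_sd = span * np.log10(src).std(ddof=1)
    return float(target_mean), float(target_sd)


def select_matched_random_sets(
    source_degrees, target: nx.Graph, spec: ProjectionSpec | None = None
) -> ProjectionResult:
    """Select a random node set whose degree mean and s.d. match the
    log-scaled source distribution (normal-degree null networks).

    Candidate sets are proposed by drawing degree values from a normal
    distribution (clipped to the target's degree range, proposal moments
    adaptively rescaled toward the targets across tries) and mapping each
    value to a distinct node of nearest degree.  A set is accepted when its
    achieved mean and s.d. are both within ``spec.tolerance`` (relative) of
    the targets; the acceptance condition is asserted on every return.
    """
    spec = spec or ProjectionSpec()
    if spec.k_max_source is None:
        raise ValueError("ProjectionSpec.k_max_source is required")
    source_degrees = np.asarray(list(source_degrees), dtype=float)
    rng = np.random.default_rng(spec.seed)
    by_degree, present = _degree_index(target)
    target_mean, target_sd = matched_set_targets(source_degrees, target, spec.k_max_source)
    n = source_degrees.size
    k_lo, k_hi = float(present[0]), float(present[-1])

    mu, sd = target_mean, max(target_sd, 1e-9)
    best = None
    for tries in range(1, spec.max_tries + 1):
        proposal = np.clip(rng.normal(mu, sd, size=n), k_lo, k_hi)
        available = {d: list(vs) for d, vs in by_degree.items()}
        nodes, degs = [], []
        for v in proposal:
            candidates = [k for k in present if available.get(int(k))]
            mapped = int(min(candidates, key=lambda k: (abs(k - v), k)))
            pool = available[mapped]
            nodes.append(pool.pop(int(rng.integers(len(pool)))))
            degs.append(mapped)
        degs = np.asarray(degs, dtype=float)
        a_mean = float(degs.mean())
        a_sd = float(degs.std(ddof=1)) if n > 1 else 0.0
        err = abs(a_mean - target_mean) / target_mean + (
            abs(a_sd - target_sd) / target_sd if target_sd > 0 else 0.0
        )
        if best is None or err < best[0]:
            best = (err, nodes, degs, a_mean, a_sd, tries)
        ok_mean = abs(a_mean - target_mean) <= spec.tolerance * target_mean
        ok_sd = target_sd == 0 or abs(a_sd - target_sd) <= spec.tolerance * target_sd
        if ok_mean and ok_sd:
            shapiro_p = float(stats.shapiro(degs).pvalue) if 3 <= n <= 5000 else None
            assert abs(a_mean - target_mean) <= spec.tolerance * target_mean
            return ProjectionResult(
                nodes=nodes,
                degrees=degs,
                achieved_mean=a_mean,
                achieved_sd=a_sd,
                target_mean=target_mean,
                target_sd=target_sd,
                shapiro_p=shapiro_p,
                tries=tries,
                meta={"k_min_target": k_lo, "k_max_target": k_hi},
            )
        # adaptive rescaling of the proposal toward the targets
        if a_mean != 0:
            mu *= np.clip(target_mean / a_mean, 0.8, 1.25)
        if a_sd > 0 and target_sd > 0:
            sd *= np.clip(target_sd / a_sd, 0.8, 1.25)
    raise RuntimeError(
        "matched-set selection exhausted max_tries="
        f"{spec.max_tries}; best candidate mean={best[3]:.2f} sd={best[4]:.2f} "
        f"(targets mean={target_mean:.2f} sd={target_sd:.2f})"
    )
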