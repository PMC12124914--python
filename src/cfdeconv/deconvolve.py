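"""Fragment-level likelihoods, tumor-burden estimation and tissue deconvolution.

The generative model: each fragment has a latent methylation rate
``p ~ Beta(alpha, beta)`` for its source class, and the fragment's CpG states
are conditionally i.i.d. Bernoulli(p). Marginalizing p gives the closed-form
ordered-sequence likelihood

    L(k, n | alpha, beta) = B(alpha + k, beta + n - k) / B(alpha, beta)

(no binomial coefficient: the fragment's specific state string is the datum;
the coefficient would cancel in every class ratio and mixture weight anyway).

Two inference routines sit on top:

* :func:`estimate_tumor_burden` — two-class mixture MLE for the tumor-derived
  fraction theta, maximizing ``sum_f log(theta L_tumor + (1-theta) L_normal)``
  over a theta grid.
* :func:`cf_deconvolve` — N-class fragment assignment with an "unknown" class
  for fragments whose top-two likelihood fold change falls below a threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.special import betaln

from cfdeconv.ingest import Fragment, _open_text
from cfdeconv.markers import BetaParams, MarkerRegion, intersect_markers

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Label of the catch-all class for ambiguous fragments.
UNKNOWN = "unknown"

DEFAULT_GRID_STEP = 1e-4
DEFAULT_FOLD_CHANGE = 2.0


def fragment_loglik(n_cpg: int, k_meth: int, params: BetaParams) -> float:
    """Log-likelihood of observing k methylated CpGs out of n under a class.

    Returns ``log B(alpha + k, beta + n - k) - log B(alpha, beta)``; always
    <= 0, and exactly 0 for a fragment with no CpGs (empty product).
    """
    if not isinstance(params, BetaParams):
        params = BetaParams(*params)
    if not 0 <= k_meth <= n_cpg:
        raise ValueError(f"need 0 <= k_meth <= n_cpg, got k={k_meth}, n={n_cpg}")
    if n_cpg == 0:
        return 0.0
    return float(
        betaln(params.alpha + k_meth, params.beta + n_cpg - k_meth)
        - betaln(params.alpha, params.beta)
    )


@dataclass(frozen=True)
class FragmentEvidence:
    """Per-(fragment, marker) class log-likelihoods.

    Log-likelihoods are <= 0; ``-inf`` encodes a class under which the
    fragment is impossible (zero likelihood).
    """

    marker_id: str
    n_cpg: int
    k_meth: int
    per_class_loglik: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0 <= self.k_meth <= self.n_cpg:
            raise ValueError(f"need 0 <= k_meth <= n_cpg, got k={self.k_meth}, n={self.n_cpg}")
        for cls, ll in self.per_class_loglik.items():
            if math.isnan(ll) or ll > 1e-12:
                raise ValueError(f"class {cls!r}: log-likelihood must be <= 0, got {ll}")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.per_class_loglik)


def evidence_for_fragment(fragment: Fragment, marker: MarkerRegion) -> FragmentEvidence:
    """Score one fragment against every class of one marker."""
    n, k = fragment.n_cpg, fragment.k_meth
    return FragmentEvidence(
        marker_id=marker.marker_id,
        n_cpg=n,
        k_meth=k,
        per_class_loglik={
            cls: fragment_loglik(n, k, params) for cls, params in marker.class_params.items()
        },
    )


def build_evidence(
    fragments: Iterable[Fragment],
    markers: Sequence[MarkerRegion],
) -> list[FragmentEvidence]:
    """Intersect fragments with markers and score every overlapping pair.

    A fragment overlapping several markers contributes one evidence record
    per marker; fragments overlapping no marker contribute nothing.
    """
    return [
        evidence_for_fragment(fragment, marker)
        for fragment, marker in intersect_markers(fragments, markers)
    ]


# ---------------------------------------------------------------------------
# two-class tumor burden (CancerDetector-style mixture MLE)
# ---------------------------------------------------------------------------


@dataclass
class TumorBurdenResult:
    """Tumor-derived cfDNA fraction estimate with its likelihood profile."""

    theta: float
    loglik_profile: tuple[tuple[float, float], ...]
    n_fragments_used: int
    n_fragments_trimmed: int

    @property
    def max_loglik(self) -> float:
        return max(ll for _, ll in self.loglik_profile)


def _mixture_profile(
    llt: np.ndarray, lln: np.ndarray, grid: np.ndarray, chunk: int = 1024
) -> np.ndarray:
    """Total mixture log-likelihood at every grid theta, overflow-safe."""
    # factor out the per-fragment max so both scaled likelihoods are <= 1
    m = np.maximum(llt, lln)
    a = np.exp(llt - m)  # tumor, in (0, 1]
    b = np.exp(lln - m)  # normal, in (0, 1]
    base = float(m.sum())
    profile = np.empty(grid.size)
    with np.errstate(divide="ignore"):
        for lo in range(0, grid.size, chunk):
            theta = grid[lo : lo + chunk, None]
            profile[lo : lo + chunk] = (
                np.log(theta * a + (1.0 - theta) * b).sum(axis=1) + base
            )
    return profile


def estimate_tumor_burden(
    evidence: Sequence[FragmentEvidence],
    grid_step: float = DEFAULT_GRID_STEP,
    trim_fraction: float = 0.0,
    tumor_class: str = "tumor",
    normal_class: str = "normal",
    refine: bool = False,
) -> TumorBurdenResult:
    """Maximum-likelihood tumor fraction from two-class fragment evidence.

    Maximizes ``sum_f log(theta L_tumor + (1 - theta) L_normal)`` over the
    grid ``{0, grid_step, ..., 1}``; ties (within 1e-9 of the maximum) break
    toward smaller theta. With ``trim_fraction > 0`` the fragments whose
    absolute log-likelihood ratio lies beyond the ``1 - trim_fraction``
    quantile are excluded first (robustness against outlier fragments).
    ``refine=True`` polishes the grid optimum with a bounded scalar search
    one grid step wide.
    """
    if not evidence:
        raise ValueError("no fragment evidence; cannot estimate tumor burden")
    if not 0.0 < grid_step <= 0.1:
        raise ValueError(f"grid_step must be in (0, 0.1], got {grid_step}")
    if not 0.0 <= trim_fraction <= 0.2:
        raise ValueError(f"trim_fraction must be in [0, 0.2], got {trim_fraction}")

    try:
        llt = np.array([e.per_class_loglik[tumor_class] for e in evidence])
        lln = np.array([e.per_class_loglik[normal_class] for e in evidence])
    except KeyError as exc:
        raise ValueError(f"evidence lacks class {exc.args[0]!r}") from None
    both_zero = np.isneginf(llt) & np.isneginf(lln)
    if both_zero.any():
        raise ValueError(
            f"{int(both_zero.sum())} fragments have zero likelihood under both "
            "classes; the mixture likelihood is degenerate"
        )

    n_trimmed = 0
    if trim_fraction > 0.0:
        score = np.abs(llt - lln)
        cutoff = np.quantile(score, 1.0 - trim_fraction)
        keep = score <= cutoff
        n_trimmed = int((~keep).sum())
        llt, lln = llt[keep], lln[keep]

    grid = np.arange(0.0, 1.0, grid_step)
    grid = np.append(grid, 1.0)
    profile = _mixture_profile(llt, lln, grid)

    best = profile.max()
    idx = int(np.flatnonzero(profile >= best - 1e-9)[0])  # smallest theta wins ties
    theta = float(grid[idx])

    if refine and 0 < idx < grid.size - 1 and np.isfinite(best):
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda t: -_mixture_profile(llt, lln, np.array([t]))[0],
            bounds=(grid[idx - 1], grid[idx + 1]),
            method="bounded",
            options={"xatol": grid_step * 1e-4},
        )
        if res.success and -res.fun >= best:
            theta = float(res.x)

    return TumorBurdenResult(
        theta=theta,
        loglik_profile=tuple(zip(grid.tolist(), profile.tolist())),
        n_fragments_used=int(llt.size),
        n_fragments_trimmed=n_trimmed,
    )


# ---------------------------------------------------------------------------
# N-class deconvolution with an unknown class (cfDeconvolve-style)
# ---------------------------------------------------------------------------


def assign_fragment(
    evidence: FragmentEvidence,
    fold_change_threshold: float = DEFAULT_FOLD_CHANGE,
) -> str:
    """Assign a fragment to its best class, or :data:`UNKNOWN` if ambiguous.

    With top-two likelihoods ``L(1) >= L(2)``, the fragment is assigned to
    the top class iff ``L(1) / L(2) >= fold_change_threshold``; an exact tie
    for first place is always :data:`UNKNOWN`. The ratio is computed in log
    space, so zero likelihoods are handled safely.
    """
    if fold_change_threshold < 1.0:
        raise ValueError(f"fold_change_threshold must be >= 1, got {fold_change_threshold}")
    if len(evidence.per_class_loglik) < 2:
        raise ValueError("need at least 2 classes to assign a fragment")
    ranked = sorted(evidence.per_class_loglik.items(), key=lambda item: -item[1])
    (top_class, l1), (_, l2) = ranked[0], ranked[1]
    if l1 == l2:
        return UNKNOWN
    if l1 - l2 >= math.log(fold_change_threshold):
        return top_class
    return UNKNOWN


@dataclass
class DeconvolutionResult:
    """Per-class unambiguous fragment counts and cfDNA fractions.

    ``fractions`` covers every class plus :data:`UNKNOWN` and sums to 1:
    ambiguous fragments are reported as the unknown component, not dropped.
    """

    class_counts: dict[str, int]
    unknown_count: int
    fractions: dict[str, float]

    @property
    def n_fragments(self) -> int:
        return sum(self.class_counts.values()) + self.unknown_count


def cf_deconvolve(
    evidence: Sequence[FragmentEvidence],
    fold_change_threshold: float = DEFAULT_FOLD_CHANGE,
) -> DeconvolutionResult:
    """Estimate cfDNA tissue fractions from N-class fragment evidence."""
    evidence = list(evidence)
    if not evidence:
        raise ValueError(
            "no fragment evidence: no fragments overlap the marker regions "
            "(check chromosome naming and marker coordinates)"
        )
    classes = evidence[0].classes
    class_set = set(classes)
    for e in evidence:
        if set(e.classes) != class_set:
            raise ValueError(
                f"inconsistent class sets across evidence: {sorted(class_set)} vs "
                f"{sorted(e.classes)}"
            )
    counts = {cls: 0 for cls in classes}
    unknown = 0
    for e in evidence:
        label = assign_fragment(e, fold_change_threshold)
        if label == UNKNOWN:
            unknown += 1
        else:
            counts[label] += 1
    total = len(evidence)
    fractions = {cls: counts[cls] / total for cls in classes}
    fractions[UNKNOWN] = unknown / total
    return DeconvolutionResult(class_counts=counts, unknown_count=unknown, fractions=fractions)


# ---------------------------------------------------------------------------
# reports and plotting
# ---------------------------------------------------------------------------


def write_tumor_burden(result: TumorBurdenResult, path: PathLike) -> None:
    """Write a one-row tumor-burden report (TSV)."""
    with _open_text(path, "wt") as handle:
        handle.write("#theta\tn_fragments_used\tn_fragments_trimmed\tloglik\n")
        handle.write(
            f"{result.theta:.6f}\t{result.n_fragments_used}\t"
            f"{result.n_fragments_trimmed}\t{result.max_loglik:.6f}\n"
        )


def write_fractions(result: DeconvolutionResult, path: PathLike) -> None:
    """Write the per-class count/fraction table (TSV), unknown last."""
    with _open_text(path, "wt") as handle:
        handle.write("#class\tcount\tfraction\n")
        for cls, count in result.class_counts.items():
            handle.write(f"{cls}\t{count}\t{result.fractions[cls]:.9f}\n")
        handle.write(f"{UNKNOWN}\t{result.unknown_count}\t{result.fractions[UNKNOWN]:.9f}\n")


def read_fractions(path: PathLike) -> dict[str, float]:
    """Read a fraction table written by :func:`write_fractions`."""
    fractions: dict[str, float] = {}
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            fractions[fields[0]] = float(fields[-1])
    return fractions


def plot_fraction_pie(
    fractions: Mapping[str, float],
    path: PathLike,
    title: str | None = None,
    tolerance: float = 1e-6,
) -> None:
    """Render a pie chart of cfDNA fractions (wedges in descending order)."""
    if any(f < 0 for f in fractions.values()):
        raise ValueError("fractions must be non-negative")
    total = sum(fractions.values())
    if abs(total - 1.0) > tolerance:
        raise ValueError(f"fractions must sum to 1 (got {total:.6g})")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(fractions.items(), key=lambda item: -item[1])
    labels = [cls for cls, _ in ordered]
    sizes = [f for _, f in ordered]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(
        sizes,
        labels=labels,
        autopct=lambda pct: f"{pct:.1f}%" if pct >= 1.0 else "",
        startangle=90,
        counterclock=False,
    )
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
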