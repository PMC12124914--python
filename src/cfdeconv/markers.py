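"""Marker regions parameterized by per-class beta distributions.

Provides method-of-moments fitting of Beta(alpha, beta) shapes from reference
beta values, the tab-delimited "alpha:beta" marker file dialect, and
fragment-marker interval intersection.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from cfdeconv.ingest import Fragment, _open_text

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEFAULT_VARIANCE_FLOOR = 1e-6
WINSOR_EPS = 1e-4


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta(alpha, beta) distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, value in (("alpha", self.alpha), ("beta", self.beta)):
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a finite positive number, got {value!r}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


@dataclass(frozen=True)
class MarkerRegion:
    """A genomic marker interval with one BetaParams per class.

    ``class_params`` preserves insertion order; classes are matched by name
    everywhere, never by column position.
    """

    chrom: str
    start: int
    end: int
    marker_id: str
    class_params: Mapping[str, BetaParams]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"marker {self.marker_id!r}: start must be < end")
        if not self.class_params:
            raise ValueError(f"marker {self.marker_id!r}: needs at least one class")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_params)


def fit_beta_params(
    values: Sequence[float],
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    winsor_eps: float = WINSOR_EPS,
    method: str = "moments",
) -> BetaParams:
    """Fit Beta(alpha, beta) shapes to reference beta values in [0, 1].

    Missing (NaN) entries are dropped; at least two usable values are
    required. Exact 0/1 values are winsorized into
    ``[winsor_eps, 1 - winsor_eps]`` to keep downstream likelihoods finite.

    The default ``moments`` estimator matches sample mean ``m`` and variance
    ``v`` (n-1 denominator, floored at ``variance_floor`` and clamped below
    ``m (1 - m)``):

        alpha = m * c,  beta = (1 - m) * c,  c = m (1 - m) / v - 1

    so the fitted mean always equals the (winsorized) sample mean exactly.
    ``method="mle"`` uses the scipy maximum-likelihood fit instead.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("beta values must lie in [0, 1]")
    if arr.size < 2:
        raise ValueError(f"need at least 2 usable beta values, got {arr.size}")
    arr = np.clip(arr, winsor_eps, 1.0 - winsor_eps)

    if method == "mle":
        alpha, beta, _, _ = stats.beta.fit(arr, floc=0.0, fscale=1.0)
        return BetaParams(float(alpha), float(beta))
    if method != "moments":
        raise ValueError(f"unknown fitting method {method!r}")

    m = float(arr.mean())
    v = float(arr.var(ddof=1))
    if v < variance_floor:
        logger.warning(
            "sample variance %.3g below floor %.3g (near-identical values); using floor",
            v,
            variance_floor,
        )
        v = variance_floor
    mv = m * (1.0 - m)
    if v >= mv:
        v = 0.99 * mv  # moment equations need v < m(1-m)
    c = mv / v - 1.0
    return BetaParams(m * c, (1.0 - m) * c)


# ---------------------------------------------------------------------------
# marker parameter file dialect
# ---------------------------------------------------------------------------

_MARKER_HEADER_FIXED = ("chrom", "start", "end", "marker_id")


def _format_shape(value: float) -> str:
    # >= 6 significant digits, round-trippable to 1e-6 absolute for
    # shapes < ~100
    return f"{value:.6f}" if value >= 0.1 else f"{value:.6g}"


def write_marker_params(markers: Sequence[MarkerRegion], path: PathLike) -> None:
    """Write markers in the tab-delimited "alpha:beta" dialect.

    Header row carries the class names; every marker must share the same
    ordered class set.
    """
    if not markers:
        raise ValueError("no markers to write")
    classes = markers[0].classes
    for marker in markers:
        if marker.classes != classes:
            raise ValueError(
                f"inconsistent class sets: marker {marker.marker_id!r} has "
                f"{marker.classes}, expected {classes}"
            )
    with _open_text(path, "wt") as handle:
        handle.write("#" + "\t".join(_MARKER_HEADER_FIXED + classes) + "\n")
        for marker in markers:
            tokens = [
                f"{_format_shape(p.alpha)}:{_format_shape(p.beta)}"
                for p in marker.class_params.values()
            ]
            handle.write(
                "\t".join([marker.chrom, str(marker.start), str(marker.end), marker.marker_id] + tokens)
                + "\n"
            )


def _parse_shape_token(token: str, path: PathLike, lineno: int, column: int) -> BetaParams:
    parts = token.split(":")
    if len(parts) != 2:
        raise ValueError(
            f"{path}:{lineno}: column {column}: expected 'alpha:beta', got {token!r}"
        )
    try:
        alpha, beta = float(parts[0]), float(parts[1])
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: column {column}: non-numeric shape in {token!r}"
        ) from None
    try:
        return BetaParams(alpha, beta)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: column {column}: {exc}") from None


def read_marker_params(path: PathLike) -> list[MarkerRegion]:
    """Read a marker parameter file written by :func:`write_marker_params`."""
    markers: list[MarkerRegion] = []
    classes: tuple[str, ...] | None = None
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if classes is None:
                header = line.lstrip("#").split("\t")
                if tuple(header[:4]) != _MARKER_HEADER_FIXED:
                    raise ValueError(
                        f"{path}:{lineno}: expected header starting with "
                        f"{_MARKER_HEADER_FIXED}, got {header[:4]}"
                    )
                classes = tuple(header[4:])
                if len(classes) < 1:
                    raise ValueError(f"{path}:{lineno}: header names no classes")
                continue
            fields = line.split("\t")
            if len(fields) != 4 + len(classes):
                raise ValueError(
                    f"{path}:{lineno}: expected {4 + len(classes)} columns, got {len(fields)}"
                )
            params = {
                cls: _parse_shape_token(token, path, lineno, col)
                for col, (cls, token) in enumerate(zip(classes, fields[4:]), start=5)
            }
            markers.append(
                MarkerRegion(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    marker_id=fields[3],
                    class_params=params,
                )
            )
    if classes is None:
        raise ValueError(f"{path}: empty marker file")
    return markers


# ---------------------------------------------------------------------------
# fitting a whole panel from a reference beta-value matrix
# ---------------------------------------------------------------------------

_REGION_ID = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region_id(marker_id: str) -> tuple[str, int, int]:
    """Parse a ``chrom:start-end`` marker id into its coordinates."""
    match = _REGION_ID.match(marker_id)
    if match is None:
        raise ValueError(
            f"marker id {marker_id!r} is not in 'chrom:start-end' form; "
            "coordinates cannot be recovered"
        )
    return match["chrom"], int(match["start"]), int(match["end"])


def fit_marker_panel(
    beta_matrix: pd.DataFrame,
    sample_classes: Mapping[str, str],
    **fit_kwargs,
) -> list[MarkerRegion]:
    """Fit per-class BetaParams for every marker of a reference matrix.

    ``beta_matrix`` has markers as rows (index = ``chrom:start-end`` ids) and
    samples as columns; ``sample_classes`` maps sample id to class name.
    """
    unknown = [s for s in beta_matrix.columns if s not in sample_classes]
    if unknown:
        raise ValueError(f"samples missing from the class mapping: {unknown[:5]}")
    classes: list[str] = []
    for sample in beta_matrix.columns:
        cls = sample_classes[sample]
        if cls not in classes:
            classes.append(cls)
    by_class = {
        cls: [s for s in beta_matrix.columns if sample_classes[s] == cls] for cls in classes
    }
    markers = []
    for marker_id, row in beta_matrix.iterrows():
        chrom, start, end = parse_region_id(str(marker_id))
        params = {
            cls: fit_beta_params(row[samples].to_numpy(dtype=float), **fit_kwargs)
            for cls, samples in by_class.items()
        }
        markers.append(MarkerRegion(chrom, start, end, str(marker_id), params))
    return markers


def read_beta_matrix(path: PathLike) -> pd.DataFrame:
    """Read a marker x sample beta-value matrix (TSV, marker ids as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_sample_classes(path: PathLike) -> dict[str, str]:
    """Read a two-column sample_id -> class mapping (TSV, header optional)."""
    mapping: dict[str, str] = {}
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: expected 2 columns, got {line!r}")
            mapping[fields[0]] = fields[1]
    return mapping


# ---------------------------------------------------------------------------
# fragment-marker intersection
# ---------------------------------------------------------------------------


def intersect_markers(
    fragments: Iterable[Fragment],
    markers: Sequence[MarkerRegion],
) -> Iterator[tuple[Fragment, MarkerRegion]]:
    """Pair each fragment with every marker it overlaps by >= 1 bp.

    Intervals are half-open, so touching boundaries do not overlap.
    Fragments overlapping no marker are dropped; a fragment overlapping
    several markers is emitted once per marker.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[MarkerRegion]]] = {}
    for marker in markers:
        by_chrom.setdefault(marker.chrom, (None, None, []))[2].append(marker)
    index = {
        chrom: (
            np.array([m.start for m in mlist]),
            np.array([m.end for m in mlist]),
            mlist,
        )
        for chrom, (_, _, mlist) in by_chrom.items()
    }
    for fragment in fragments:
        entry = index.get(fragment.chrom)
        if entry is None:
            continue
        starts, ends, mlist = entry
        hits = np.flatnonzero((starts < fragment.end) & (ends > fragment.start))
        for i in hits:
            yield fragment, mlist[i]
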