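"""Ground-truthed synthetic inputs for the whole pipeline.

Generates marker panels, fragment populations from known tissue mixtures,
reference beta-value matrices, and Bismark-dialect read/call files, so every
other module is testable without any external data.

The generative model mirrors the likelihood model used for inference: a
fragment draws its class from the mixture, a marker uniformly at random, a
latent methylation rate ``p ~ Beta(alpha_class, beta_class)`` for that
marker, and i.i.d. Bernoulli(p) CpG states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from cfdeconv.ingest import METHYLATED, UNMETHYLATED, Fragment, _open_text
from cfdeconv.markers import BetaParams, MarkerRegion

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SimulationConfig:
    """Declarative description of one synthetic dataset.

    ``class_params[cls]`` holds one :class:`BetaParams` per marker. Markers
    are laid out as non-overlapping fixed-width intervals on a toy
    chromosome. Defaults echo typical cfDNA: fragment lengths ~
    normal(167, 20) truncated to [80, 400], 3-8 CpGs per fragment.
    """

    class_names: tuple[str, ...]
    mixture: Mapping[str, float]
    class_params: Mapping[str, tuple[BetaParams, ...]]
    n_markers: int = 20
    n_fragments: int = 5000
    cpg_min: int = 3
    cpg_max: int = 8
    length_mean: float = 167.0
    length_sd: float = 20.0
    length_min: int = 80
    length_max: int = 400
    marker_width: int = 1000
    marker_gap: int = 500
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_names) < 1:
            raise ValueError("need at least one class")
        if set(self.mixture) != set(self.class_names):
            raise ValueError("mixture classes must match class_names")
        weights = [self.mixture[c] for c in self.class_names]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture must be non-negative and sum to 1, got {weights}")
        if set(self.class_params) != set(self.class_names):
            raise ValueError("class_params classes must match class_names")
        for cls, params in self.class_params.items():
            if len(params) != self.n_markers:
                raise ValueError(
                    f"class {cls!r}: expected {self.n_markers} per-marker params, "
                    f"got {len(params)}"
                )
        if self.n_fragments < 1 or self.n_markers < 1:
            raise ValueError("n_fragments and n_markers must be positive")
        if not 0 <= self.cpg_min <= self.cpg_max:
            raise ValueError("need 0 <= cpg_min <= cpg_max")
        if not 2 <= self.length_min <= self.length_max:
            raise ValueError("need 2 <= length_min <= length_max")
        if self.cpg_max > self.length_min:
            raise ValueError("cpg_max must not exceed length_min (CpG sites are distinct bases)")

    @classmethod
    def uniform_markers(
        cls,
        class_betas: Mapping[str, BetaParams],
        mixture: Mapping[str, float],
        n_markers: int = 20,
        **kwargs,
    ) -> "SimulationConfig":
        """Config where every marker shares the same per-class shapes."""
        names = tuple(class_betas)
        return cls(
            class_names=names,
            mixture=dict(mixture),
            class_params={c: (class_betas[c],) * n_markers for c in names},
            n_markers=n_markers,
            **kwargs,
        )


@dataclass(frozen=True)
class SimulatedFragment:
    """A fragment together with its generative ground truth."""

    fragment: Fragment
    label: str
    marker_id: str
    meth_rate: float


@dataclass
class SimulationResult:
    config: SimulationConfig
    markers: list[MarkerRegion]
    fragments: list[SimulatedFragment]

    def fragment_list(self) -> list[Fragment]:
        return [sf.fragment for sf in self.fragments]

    def truth(self) -> dict[str, str]:
        return {sf.fragment.fragment_id: sf.label for sf in self.fragments}

    def write_truth(self, path: PathLike) -> None:
        with _open_text(path, "wt") as handle:
            handle.write("#fragment_id\tclass\n")
            for sf in self.fragments:
                handle.write(f"{sf.fragment.fragment_id}\t{sf.label}\n")


def build_marker_panel(config: SimulationConfig) -> list[MarkerRegion]:
    """Non-overlapping fixed-width markers on the toy chromosome."""
    markers = []
    for i in range(config.n_markers):
        start = 1000 + i * (config.marker_width + config.marker_gap)
        end = start + config.marker_width
        marker_id = f"{config.chrom}:{start}-{end}"
        markers.append(
            MarkerRegion(
                chrom=config.chrom,
                start=start,
                end=end,
                marker_id=marker_id,
                class_params={
                    cls: config.class_params[cls][i] for cls in config.class_names
                },
            )
        )
    return markers


def simulate_fragments(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationResult:
    """Draw a ground-truthed fragment population from the config.

    Fragment starts are uniform over their marker, so every fragment overlaps
    exactly its own marker (the gap exceeds the maximum fragment length).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    markers = build_marker_panel(config)
    n = config.n_fragments
    weights = np.array([config.mixture[c] for c in config.class_names])
    class_idx = rng.choice(len(config.class_names), size=n, p=weights)
    marker_idx = rng.integers(0, config.n_markers, size=n)

    a, b = (
        (config.length_min - config.length_mean) / config.length_sd,
        (config.length_max - config.length_mean) / config.length_sd,
    )
    lengths = stats.truncnorm.rvs(
        a, b, loc=config.length_mean, scale=config.length_sd, size=n, random_state=rng
    ).astype(int)
    lengths = np.clip(lengths, config.length_min, config.length_max)

    n_cpgs = rng.integers(config.cpg_min, config.cpg_max + 1, size=n)

    fragments: list[SimulatedFragment] = []
    for i in range(n):
        cls = config.class_names[class_idx[i]]
        marker = markers[marker_idx[i]]
        params = config.class_params[cls][marker_idx[i]]
        length = int(lengths[i])
        start = marker.start + int(rng.integers(0, config.marker_width))
        n_cpg = int(n_cpgs[i])
        offsets = np.sort(rng.choice(length, size=n_cpg, replace=False))
        p = float(rng.beta(params.alpha, params.beta))
        states = rng.random(n_cpg) < p
        fragments.append(
            SimulatedFragment(
                fragment=Fragment(
                    fragment_id=f"frag{i:06d}",
                    chrom=config.chrom,
                    start=start,
                    end=start + length,
                    cpg_positions=tuple(int(start + o) for o in offsets),
                    meth_state="".join(METHYLATED if s else UNMETHYLATED for s in states),
                ),
                label=cls,
                marker_id=marker.marker_id,
                meth_rate=p,
            )
        )
    return SimulationResult(config=config, markers=markers, fragments=fragments)


def simulate_reference_matrix(
    config: SimulationConfig,
    n_samples_per_class: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-marker beta values across reference samples of known class.

    Returns a marker x sample matrix (index = ``chrom:start-end`` marker ids)
    and the sample -> class mapping, for exercising marker-parameter fitting.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    markers = build_marker_panel(config)
    columns: dict[str, np.ndarray] = {}
    sample_classes: dict[str, str] = {}
    for cls in config.class_names:
        alphas = np.array([p.alpha for p in config.class_params[cls]])
        betas = np.array([p.beta for p in config.class_params[cls]])
        for j in range(n_samples_per_class):
            sample_id = f"{cls}_s{j:02d}"
            columns[sample_id] = rng.beta(alphas, betas)
            sample_classes[sample_id] = cls
    matrix = pd.DataFrame(columns, index=[m.marker_id for m in markers])
    return matrix, sample_classes


def write_beta_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="marker_id", float_format="%.6f")


def write_sample_classes(sample_classes: Mapping[str, str], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("#sample_id\tclass\n")
        for sample, cls in sample_classes.items():
            handle.write(f"{sample}\t{cls}\n")


# ---------------------------------------------------------------------------
# Bismark-dialect emission
# ---------------------------------------------------------------------------


@dataclass
class EmitResult:
    """Paths and tallies from :func:`emit_bismark_dialect`."""

    bed_path: Path
    calls_ot_path: Path
    calls_ob_path: Path
    n_fragments: int
    n_duplicated_cpgs: int
    n_conflicts_injected: int


def emit_bismark_dialect(
    fragments: Sequence[Fragment],
    outdir: PathLike,
    mate_overlap: float = 0.4,
    conflict_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EmitResult:
    """Write fragments as paired-end BED + CpG_OT/CpG_OB call files.

    Each fragment is split into two mates overlapping by ``mate_overlap`` of
    its length (at least 1 bp), with mate 1 written as an OT-strand read and
    mate 2 as OB. CpGs in the overlap are reported by both mates, exercising
    the duplicate-agreement merge path; with probability ``conflict_rate``
    a duplicated CpG's OB copy is flipped, exercising the conflict-drop path
    (such CpGs vanish from the re-ingested fragment).

    OB call positions are written 1-based on the G of the CpG, i.e. the exact
    inverse of the ingestion normalization.
    """
    if not 0.0 <= mate_overlap < 1.0:
        raise ValueError(f"mate_overlap must be in [0, 1), got {mate_overlap}")
    if not 0.0 <= conflict_rate <= 1.0:
        raise ValueError(f"conflict_rate must be in [0, 1], got {conflict_rate}")
    if rng is None:
        rng = np.random.default_rng(0)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed_path = outdir / "reads.bed"
    ot_path = outdir / "CpG_OT_reads.txt"
    ob_path = outdir / "CpG_OB_reads.txt"

    n_dup = 0
    n_conflict = 0
    with _open_text(bed_path, "wt") as bed, _open_text(ot_path, "wt") as ot, _open_text(
        ob_path, "wt"
    ) as ob:
        ot.write("Bismark methylation extractor version synthetic\n")
        ob.write("Bismark methylation extractor version synthetic\n")
        for frag in fragments:
            length = frag.length
            if length < 2:  # too short to split: emit as a singleton mate
                bed.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.fragment_id}/1\t0\t+\n")
                for pos, state in zip(frag.cpg_positions, frag.meth_state):
                    meth = state == METHYLATED
                    ot.write(
                        f"{frag.fragment_id}/1\t{'+' if meth else '-'}\t{frag.chrom}\t"
                        f"{pos + 1}\t{'Z' if meth else 'z'}\n"
                    )
                continue
            overlap_len = min(max(1, int(round(length * mate_overlap))), length - 1)
            half = (length + overlap_len) // 2
            m1_end = frag.start + half
            m2_start = m1_end - overlap_len
            bed.write(f"{frag.chrom}\t{frag.start}\t{m1_end}\t{frag.fragment_id}/1\t0\t+\n")
            bed.write(f"{frag.chrom}\t{m2_start}\t{frag.end}\t{frag.fragment_id}/2\t0\t-\n")
            for pos, state in zip(frag.cpg_positions, frag.meth_state):
                meth = state == METHYLATED
                on_mate1 = pos < m1_end
                on_mate2 = pos >= m2_start
                ob_meth = meth
                if on_mate1 and on_mate2:
                    n_dup += 1
                    if conflict_rate > 0.0 and rng.random() < conflict_rate:
                        ob_meth = not meth
                        n_conflict += 1
                if on_mate1:
                    ot.write(
                        f"{frag.fragment_id}/1\t{'+' if meth else '-'}\t{frag.chrom}\t"
                        f"{pos + 1}\t{'Z' if meth else 'z'}\n"
                    )
                if on_mate2:
                    ob.write(
                        f"{frag.fragment_id}/2\t{'+' if ob_meth else '-'}\t{frag.chrom}\t"
                        f"{pos + 2}\t{'Z' if ob_meth else 'z'}\n"
                    )
    return EmitResult(
        bed_path=bed_path,
        calls_ot_path=ot_path,
        calls_ob_path=ob_path,
        n_fragments=len(fragments),
        n_duplicated_cpgs=n_dup,
        n_conflicts_injected=n_conflict,
    )


# ---------------------------------------------------------------------------
# key = value config files for the CLI
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA = """\
Simulation config: one "key = value" per line, '#' comments.

  classes       comma-separated class names                   (required)
  mixture       comma-separated fractions, same order, sum 1  (required)
  beta.<class>  "alpha:beta" shapes for that class            (required per class)
  n_markers, n_fragments, cpg_min, cpg_max, length_mean, length_sd,
  length_min, length_max, marker_width, marker_gap, chrom, seed   (optional)
"""

_INT_KEYS = {
    "n_markers",
    "n_fragments",
    "cpg_min",
    "cpg_max",
    "length_min",
    "length_max",
    "marker_width",
    "marker_gap",
    "seed",
}
_FLOAT_KEYS = {"length_mean", "length_sd"}


def parse_config(path: PathLike) -> SimulationConfig:
    """Parse a key = value simulation config file. Schema::

    %s
    """ % _CONFIG_SCHEMA
    raw: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value
    for required in ("classes", "mixture"):
        if required not in raw:
            raise ValueError(f"{path}: missing required key {required!r}")
    names = tuple(c.strip() for c in raw.pop("classes").split(","))
    weights = [float(w) for w in raw.pop("mixture").split(",")]
    if len(weights) != len(names):
        raise ValueError(f"{path}: {len(names)} classes but {len(weights)} mixture weights")
    betas: dict[str, BetaParams] = {}
    for cls in names:
        key = f"beta.{cls}"
        if key not in raw:
            raise ValueError(f"{path}: missing required key {key!r}")
        alpha, beta = (float(v) for v in raw.pop(key).split(":"))
        betas[cls] = BetaParams(alpha, beta)
    kwargs: dict[str, object] = {}
    for key, value in raw.items():
        if key in _INT_KEYS:
            kwargs[key] = int(value)
        elif key in _FLOAT_KEYS:
            kwargs[key] = float(value)
        elif key == "chrom":
            kwargs[key] = value
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    n_markers = int(kwargs.pop("n_markers", 20))
    return SimulationConfig.uniform_markers(
        betas, dict(zip(names, weights)), n_markers=n_markers, **kwargs
    )
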