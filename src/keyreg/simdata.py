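"""Synthetic two-state expression data with planted key regulators.

The generator emulates a simple causal structure: ``m`` regulators, of
which ``k`` "bona fide" key regulators carry a mean shift between two
sample groups; every regulator drives ``t`` targets (``t`` drawn uniformly
from ``[targets_min, targets_max]``), each target being the regulator's
expression plus i.i.d. Gaussian noise.  With the defaults (m=500,
t ~ U{3..50}) a realization has 500 + sum(t) genes, i.e. about 13,750
in expectation.

Because targets literally copy their regulator's signal, a planted key
regulator is (a) differentially expressed and (b) has a differentially
expressed regulon — exactly the pattern the ranking stage rewards — which
makes the generator a ground-truth benchmark for the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionData

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_regulators",
    "downsample",
    "simulate_knockdown",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the two-group planted-regulator simulation.

    Attributes
    ----------
    n_samples : int
        Total samples; split as evenly as possible into groups A and B.
    n_regulators : int
        Number of regulators (m).
    n_bona_fide : int
        Number of planted (differential) key regulators (k <= m).
    targets_min, targets_max : int
        Bounds of the per-regulator target count t (uniform integer draw).
    effect_size : float
        Group-B mean shift of each bona fide regulator, in expression
        units.  Default 2.0 = two baseline standard deviations.
    reg_sd : float
        Within-group standard deviation of every regulator.
    target_noise_sd : float
        Standard deviation of the Gaussian noise added when propagating a
        regulator's expression to each of its targets.
    seed : int
        RNG seed; the realization is a deterministic function of the spec.
    counts : bool
        If True, exponentiate (base 2) and Poisson-sample to emit integer
        counts instead of continuous values.
    """

    n_samples: int = 100
    n_regulators: int = 500
    n_bona_fide: int = 20
    targets_min: int = 3
    targets_max: int = 50
    effect_size: float = 2.0
    reg_sd: float = 1.0
    target_noise_sd: float = 1.0
    seed: int = 0
    counts: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4 to form two usable groups")
        if self.n_regulators < 1:
            raise ValueError("n_regulators must be positive")
        if not 0 <= self.n_bona_fide <= self.n_regulators:
            raise ValueError("need 0 <= n_bona_fide <= n_regulators")
        if not 1 <= self.targets_min <= self.targets_max:
            raise ValueError("need 1 <= targets_min <= targets_max")
        if self.reg_sd <= 0 or self.target_noise_sd <= 0:
            raise ValueError("standard deviations must be > 0")


@dataclass
class SimulatedDataset:
    """A realized simulation: expression + ground truth."""

    expression: ExpressionData
    truth: list[str]                    # bona fide regulator IDs
    target_map: dict[str, list[str]]    # regulator ID -> target IDs
    spec: SimulationSpec | None = None

    @property
    def regulators(self) -> list[str]:
        return list(self.target_map)


def _gene_ids(m: int, t_counts: np.ndarray) -> tuple[list[str], dict[str, list[str]]]:
    width = max(4, len(str(m)))
    regs = [f"REG{i + 1:0{width}d}" for i in range(m)]
    target_map = {}
    for i, r in enumerate(regs):
        target_map[r] = [f"{r}.T{j + 1:02d}" for j in range(int(t_counts[i]))]
    return regs, target_map


def simulate_regulators(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one realization of the planted-regulator simulation.

    Regulator baselines are drawn once per regulator from N(10, 2); the
    first ``n_bona_fide`` regulators get a ``+effect_size`` mean shift in
    group B.  Each target column equals its regulator's column plus
    N(0, target_noise_sd) noise, so the total gene count is exactly
    ``n_regulators + sum(t_i)``.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_regulators, spec.n_samples
    n_a = (n + 1) // 2
    groups = np.array(["A"] * n_a + ["B"] * (n - n_a))

    t_counts = rng.integers(spec.targets_min, spec.targets_max + 1, size=m)
    regs, target_map = _gene_ids(m, t_counts)
    bona_fide = regs[: spec.n_bona_fide]

    baselines = rng.normal(10.0, 2.0, size=m)
    reg_expr = baselines[:, None] + rng.normal(0.0, spec.reg_sd, size=(m, n))
    if spec.n_bona_fide:
        reg_expr[: spec.n_bona_fide, groups == "B"] += spec.effect_size

    blocks = [reg_expr]
    gene_ids = list(regs)
    for i, r in enumerate(regs):
        t = int(t_counts[i])
        noise = rng.normal(0.0, spec.target_noise_sd, size=(t, n))
        blocks.append(reg_expr[i][None, :] + noise)
        gene_ids.extend(target_map[r])
    matrix = np.vstack(blocks)

    kind = "continuous"
    if spec.counts:
        lam = np.exp2(np.clip(matrix, None, 30.0))
        matrix = rng.poisson(lam).astype(float)
        kind = "counts"

    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    values = pd.DataFrame(matrix, index=gene_ids, columns=sample_ids)
    ann = pd.DataFrame({"group": groups}, index=sample_ids)
    expr = ExpressionData(values=values, annotations=ann, kind=kind)
    return SimulatedDataset(expression=expr, truth=bona_fide, target_map=target_map, spec=spec)


def downsample(ds: SimulatedDataset, n: int, seed: int = 0) -> SimulatedDataset:
    """Subsample ``n`` samples (n/2 per group, without replacement).

    ``n`` must be even to preserve group balance, and at most the current
    sample count.  Genes and ground truth are unchanged.  ``n`` equal to
    the current (even) sample count returns the identical dataset.
    """
    expr = ds.expression
    if n % 2 != 0:
        raise ValueError(f"n must be even to keep groups balanced, got {n}")
    if n > expr.n_samples:
        raise ValueError(f"cannot draw {n} samples from {expr.n_samples}")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for g in ("A", "B"):
        pool = [s for s, lbl in expr.groups.items() if lbl == g]
        if n // 2 > len(pool):
            raise ValueError(f"group {g} has only {len(pool)} samples, need {n // 2}")
        if n // 2 == len(pool):
            chosen = pool
        else:
            chosen = sorted(rng.choice(pool, size=n // 2, replace=False).tolist())
        keep.extend(chosen)
    return SimulatedDataset(
        expression=expr.subset_samples(keep),
        truth=list(ds.truth),
        target_map={r: list(t) for r, t in ds.target_map.items()},
        spec=ds.spec,
    )


def simulate_knockdown(
    ds: SimulatedDataset,
    regulator_id: str,
    knock_fraction: float,
    seed: int = 0,
    silenced_group: str = "B",
) -> SimulatedDataset:
    """Silence one regulator in one group and re-propagate its targets.

    In the silenced group the regulator's expression is multiplied by
    ``knock_fraction`` and each of its targets is shifted by the same
    reduction (target = knocked regulator + the original noise draw), so
    the propagation is exact and deterministic.  All other genes are
    untouched.  ``knock_fraction`` must lie strictly in (0, 1).
    """
    if not 0.0 < knock_fraction < 1.0:
        raise ValueError("knock_fraction must be in (0, 1)")
    if regulator_id not in ds.target_map:
        raise ValueError(f"unknown regulator: {regulator_id!r}")
    del seed  # propagation reuses the original noise; kept for API symmetry
    expr = ds.expression
    values = expr.values.copy()
    mask = (expr.groups == silenced_group).to_numpy()
    reg_row = values.loc[regulator_id].to_numpy().copy()
    reduction = (1.0 - knock_fraction) * reg_row[mask]
    values.loc[regulator_id, values.columns[mask]] = reg_row[mask] - reduction
    for tgt in ds.target_map[regulator_id]:
        values.loc[tgt, values.columns[mask]] -= reduction
    return SimulatedDataset(
        expression=ExpressionData(values=values, annotations=expr.annotations, kind=expr.kind),
        truth=list(ds.truth),
        target_map={r: list(t) for r, t in ds.target_map.items()},
        spec=ds.spec,
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Persist expression, metadata, truth list and target map as TSV/text."""
    from pathlib import Path

    from .io import write_expression, write_metadata

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(ds.expression, out / "expression.tsv")
    write_metadata(ds.expression, out / "metadata.tsv")
    (out / "truth_regulators.txt").write_text("".join(f"{r}\n" for r in ds.truth))
    with open(out / "target_map.tsv", "w") as fh:
        fh.write("regulator\ttarget\n")
        for r, targets in ds.target_map.items():
            for t in targets:
                fh.write(f"{r}\t{t}\n")
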