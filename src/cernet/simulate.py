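"""Synthetic two-group expression data with planted ceRNA structure.

The generator emulates the statistical skeleton the analysis assumes, so
every downstream stage has a known ground truth:

* a two-group design (default 3 biological replicates per group);
* background features per RNA class — mutually independent log-normal
  abundances (log2 baseline ~ Normal(baseline_log2_mean, baseline_log2_sd),
  per-sample additive log2 noise of sd ``noise_sd``);
* planted (ceRNA, miRNA, mRNA) triads coupled through a latent per-sample
  follicle-state signal z_s: the miRNA decreases in z
  (log2 = a - planted_log2fc * z_s + eps) while ceRNA and mRNA increase
  (log2 = c + planted_log2fc * z_s + eps), eps ~ Normal(0, noise_sd^2).
  z_s is the group indicator plus a stratified within-group offset pattern
  (evenly spaced in [-latent_sd, +latent_sd], shuffled independently within
  each group and per triad): replicate pools differ systematically in
  follicle state, the offsets sum to zero within each group (so the planted
  group contrast is exactly planted_log2fc on the log2 scale), and the
  within-group ordering of z is noise-free, so planted correlations are
  perfect at noise_sd = 0 and degrade gracefully as noise_sd grows. Latent
  coupling (rather than copying one vector into another) keeps the three
  member profiles distinct;
* optional standalone planted DE mRNAs whose group means differ by
  ``planted_log2fc``;
* a target table holding the true (miRNA -> ceRNA) and (miRNA -> mRNA) rows
  plus decoy rows pointing background miRNAs at background long RNAs;
* gene intervals on a synthetic chromosome with controlled spacings — one
  lncRNA exactly 10,000 bp from a protein-coding gene and one exactly
  10,001 bp away, to exercise the cis-window boundary.

Expression is emitted as 2**(log2 value), so all abundances are positive.
All randomness flows from the single integer ``seed``; the same seed yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    AnnotationIntervals,
    ExpressionMatrix,
    TargetTable,
    ValidationError,
)
from . import io as cio

#: background features per class for the canonical fixture. The miRNA
#: universe deliberately exceeds 20: a ceRNA pair sharing its sole miRNA has
#: hypergeometric p = 1/N, so N must be large enough for a genuine sponge
#: pair to clear p < 0.05 (real transcriptomes carry hundreds of expressed
#: miRNAs; fixture scale keeps the same regime at desk size).
DEFAULT_BACKGROUND = {"mRNA": 20, "lncRNA": 10, "circRNA": 6, "miRNA": 24}

#: seed of the canonical in-repo fixture
FIXTURE_SEED = 20_250_806

TRUTH_COLUMNS = ["kind", "cerna_id", "cerna_class", "mirna_id", "mrna_id", "feature_id", "direction"]


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the canonical study conditions."""

    n_background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    n_planted_triads: int = 5
    n_planted_de: int = 0
    n_samples_per_group: int = 3
    planted_log2fc: float = 1.5
    noise_sd: float = 0.1
    latent_sd: float = 0.15
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    decoy_target_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_background.items():
            if cls not in DEFAULT_BACKGROUND:
                raise ValidationError(f"unknown RNA class {cls!r} in n_background")
            if n < 0:
                raise ValidationError(f"n_background[{cls!r}] must be >= 0")
        for name in ("n_planted_triads", "n_planted_de", "n_samples_per_group"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_samples_per_group < 2:
            raise ValidationError("n_samples_per_group must be >= 2")
        for name in ("noise_sd", "latent_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.decoy_target_fraction <= 1:
            raise ValidationError("decoy_target_fraction must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth emitted with every simulated dataset."""

    triads: pd.DataFrame  # cerna_id, cerna_class, mirna_id, mrna_id
    de_directions: pd.DataFrame  # feature_id, direction
    config: SimulationConfig

    def triad_tuples(self) -> set[tuple[str, str, str]]:
        return {
            (t.cerna_id, t.mirna_id, t.mrna_id)
            for t in self.triads.itertuples(index=False)
        }


def canonical_config(seed: int = FIXTURE_SEED, **overrides) -> SimulationConfig:
    """The canonical fixture: 6 samples, 60 background features, 5 triads."""
    cfg = SimulationConfig(seed=seed, noise_sd=0.05)
    return replace(cfg, **overrides) if overrides else cfg


def _triad_ids(i: int) -> tuple[str, str, str, str]:
    cerna_class = "lncRNA" if i % 2 == 0 else "circRNA"
    tag = "lnc" if cerna_class == "lncRNA" else "circ"
    return (f"planted_{tag}_{i:02d}", cerna_class, f"planted_mir_{i:02d}", f"planted_mrna_{i:02d}")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TargetTable, AnnotationIntervals, PlantedTruth]:
    """Draw one dataset (expression, targets, intervals, truth) from the model."""
    rng = np.random.default_rng(config.seed)
    ns = 2 * config.n_samples_per_group
    sample_ids = [f"A{i + 1}" for i in range(config.n_samples_per_group)] + [
        f"B{i + 1}" for i in range(config.n_samples_per_group)
    ]
    groups = pd.Series(
        ["groupA"] * config.n_samples_per_group + ["groupB"] * config.n_samples_per_group,
        index=sample_ids,
        dtype=object,
    )
    g_ind = np.array([0.0] * config.n_samples_per_group + [1.0] * config.n_samples_per_group)

    feature_ids: list[str] = []
    classes: list[str] = []
    log2_rows: list[np.ndarray] = []

    # background: independent log-normal features
    for cls in ("mRNA", "lncRNA", "circRNA", "miRNA"):
        n = config.n_background.get(cls, 0)
        baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
        noise = rng.normal(0.0, config.noise_sd, (n, ns))
        for j in range(n):
            feature_ids.append(f"bg_{cls.lower()}_{j:03d}")
            classes.append(cls)
            log2_rows.append(baselines[j] + noise[j])

    # planted triads: latent-signal coupling
    truth_triads = []
    de_truth: list[tuple[str, str]] = []
    target_rows: list[tuple[str, str, str]] = []
    npg = config.n_samples_per_group
    offsets = np.linspace(-1.0, 1.0, npg) * config.latent_sd
    for i in range(config.n_planted_triads):
        cerna_id, cerna_class, mirna_id, mrna_id = _triad_ids(i)
        z = g_ind + np.concatenate([rng.permutation(offsets), rng.permutation(offsets)])
        bases = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, 3)
        eps = rng.normal(0.0, config.noise_sd, (3, ns))
        rows = {
            cerna_id: (cerna_class, bases[0] + config.planted_log2fc * z + eps[0], "up"),
            mirna_id: ("miRNA", bases[1] - config.planted_log2fc * z + eps[1], "down"),
            mrna_id: ("mRNA", bases[2] + config.planted_log2fc * z + eps[2], "up"),
        }
        for fid, (cls, log2_row, direction) in rows.items():
            feature_ids.append(fid)
            classes.append(cls)
            log2_rows.append(log2_row)
            de_truth.append((fid, direction))
        truth_triads.append((cerna_id, cerna_class, mirna_id, mrna_id))
        target_rows.append((mirna_id, cerna_id, cerna_class))
        target_rows.append((mirna_id, mrna_id, "mRNA"))

    # standalone planted DE mRNAs (alternating directions)
    for i in range(config.n_planted_de):
        fid = f"planted_de_{i:02d}"
        sign = 1.0 if i % 2 == 0 else -1.0
        base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)
        noise = rng.normal(0.0, config.noise_sd, ns)
        feature_ids.append(fid)
        classes.append("mRNA")
        log2_rows.append(base + sign * config.planted_log2fc * g_ind + noise)
        de_truth.append((fid, "up" if sign > 0 else "down"))

    values = pd.DataFrame(
        np.power(2.0, np.vstack(log2_rows)) if log2_rows else np.empty((0, ns)),
        index=feature_ids,
        columns=sample_ids,
        dtype=float,
    )
    matrix = ExpressionMatrix(
        values=values,
        feature_class=pd.Series(classes, index=feature_ids, dtype=object),
        group_of_sample=groups,
    )

    targets = _with_decoys(target_rows, matrix, config, rng)
    intervals = _synthetic_intervals(matrix)
    truth = PlantedTruth(
        triads=pd.DataFrame(truth_triads, columns=["cerna_id", "cerna_class", "mirna_id", "mrna_id"]),
        de_directions=pd.DataFrame(de_truth, columns=["feature_id", "direction"]),
        config=config,
    )
    return matrix, targets, intervals, truth


def _with_decoys(
    true_rows: list[tuple[str, str, str]],
    matrix: ExpressionMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TargetTable:
    """Append decoy prediction rows pointing background miRNAs at background RNAs."""
    f = config.decoy_target_fraction
    n_true = len(true_rows)
    if f <= 0:
        n_decoy = 0
    elif n_true == 0 or f >= 1:
        n_decoy = 20  # decoy-only table for null datasets
    else:
        n_decoy = int(round(n_true * f / (1 - f)))
    bg_mirnas = sorted(m for m in matrix.features_of_class("miRNA") if m.startswith("bg_"))
    bg_long = sorted(
        fid
        for fid in matrix.feature_ids
        if fid.startswith("bg_") and matrix.feature_class[fid] != "miRNA"
    )
    rows = list(true_rows)
    if n_decoy and bg_mirnas and bg_long:
        seen = set(true_rows)
        attempts = 0
        while len(rows) - n_true < n_decoy and attempts < 100 * n_decoy:
            attempts += 1
            mirna = bg_mirnas[int(rng.integers(len(bg_mirnas)))]
            target = bg_long[int(rng.integers(len(bg_long)))]
            key = (mirna, target, matrix.feature_class[target])
            if key in seen:
                continue
            seen.add(key)
            rows.append(key)
    df = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])
    df["site_count"] = 1
    return TargetTable.from_records(df)


def _synthetic_intervals(matrix: ExpressionMatrix) -> AnnotationIntervals:
    """Lay long-RNA loci on synthetic chromosomes with controlled spacings.

    Protein-coding genes sit at 30 kb intervals on ``chr_sim``. The first
    lncRNA is placed a gap of exactly 10,000 bp downstream of gene 0, the
    second 10,001 bp downstream of gene 1; remaining lncRNAs sit 2,000 bp
    from their partner gene. circRNA loci live on a separate chromosome so
    they never enter cis assignment.
    """
    genes = matrix.features_of_class("mRNA")
    lncs = matrix.features_of_class("lncRNA")
    circs = matrix.features_of_class("circRNA")
    recs = []
    for i, gid in enumerate(genes):
        start = 30_000 * i
        recs.append((gid, "chr_sim", start, start + 1_000, "+", "protein_coding"))
    for j, lid in enumerate(lncs):
        if j == 0 and len(genes) > 0:
            start = 30_000 * 0 + 1_000 + 10_000  # gap exactly 10,000 to gene 0
        elif j == 1 and len(genes) > 1:
            start = 30_000 * 1 + 1_000 + 10_001  # gap exactly 10,001 to gene 1
        elif j < len(genes):
            start = 30_000 * j + 1_000 + 2_000  # comfortably cis to gene j
        else:
            start = 30_000 * (len(genes) + j)  # isolated: no gene within reach
        recs.append((lid, "chr_sim", start, start + 500, "-", "lncRNA"))
    for k, cid in enumerate(circs):
        start = 5_000 * k
        recs.append((cid, "chr_sim_circ", start, start + 300, ".", "other"))
    return AnnotationIntervals(
        records=pd.DataFrame(
            recs, columns=["feature_id", "chrom", "start", "end", "strand", "biotype"]
        )
    )


def write_truth(truth: PlantedTruth, path) -> None:
    """Write ground truth as TSV (documented header, one record per row)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth.triads.itertuples(index=False):
            fh.write(f"triad\t{t.cerna_id}\t{t.cerna_class}\t{t.mirna_id}\t{t.mrna_id}\t\t\n")
        for d in truth.de_directions.itertuples(index=False):
            fh.write(f"de\t\t\t\t\t{d.feature_id}\t{d.direction}\n")


def read_truth(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a truth TSV back into (triads, de_directions) frames."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    triads = df[df["kind"] == "triad"][["cerna_id", "cerna_class", "mirna_id", "mrna_id"]]
    de = df[df["kind"] == "de"][["feature_id", "direction"]]
    return triads.reset_index(drop=True), de.reset_index(drop=True)


def emit_fixture_suite(outdir, seed: int = FIXTURE_SEED) -> dict[str, str]:
    """Write the canonical fixture (4 data files + 1 truth file) to ``outdir``.

    Re-running with the same seed reproduces the files byte for byte.
    Returns a name -> path map.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, targets, intervals, truth = simulate_dataset(canonical_config(seed=seed))
    paths = {
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.tsv",
        "targets": outdir / "targets.tsv",
        "annotation": outdir / "annotation.gtf",
        "truth": outdir / "truth.tsv",
    }
    cio.write_expression(matrix, paths["expression"])
    cio.write_design(matrix.group_of_sample, matrix.feature_class, paths["design"])
    cio.write_target_table(targets, paths["targets"])
    cio.write_gtf(intervals, paths["annotation"])
    write_truth(truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
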