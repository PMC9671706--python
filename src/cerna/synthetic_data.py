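"""Synthetic case/control study generator with known ground truth.

Emulates a post-mortem brain microarray cohort: a log-normal background
expression matrix with planted two-group effects, planted ceRNA axes whose
lncRNA and mRNA share a latent per-sample factor (the co-expression the
sponging mechanism induces), age/gender covariate effects on a fraction of
genes, and matching interaction / PPI / pathway files.  Everything is
deterministic under (config, seed) and every planted structure is recorded
in a :class:`GroundTruth` object, the oracle for recovery tests.

Modelling notes
---------------
* miRNAs are unobserved (arrays do not measure mature miRNAs), so axis
  co-expression is induced directly by a shared latent factor rather than
  by explicit miRNA kinetics — it is exactly the signal the pipeline's
  correlation gate can detect.
* On the log2 scale a planted gene in sample s is

      baseline_g + beta_g * case(s) + f_axis(s) + age/gender terms + noise

  with beta_g = +/- de_log2fc and f_axis ~ N(0, axis_latent_sd^2) shared by
  the axis's lncRNA and mRNA.  The matrix is returned as 2^signal (linear).
* Planted DE and axis genes draw their baselines from the upper expression
  range (detected transcripts are well expressed on arrays), so the
  intensity and IQR filters act on the background, not on the truth.
* Decoy interaction edges touch only non-DE genes by default, making the
  planted axes the unique expected output; ``hard_decoys=True`` adds edges
  between oppositely-regulated DE genes to exercise the sign gate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ConsistencyError,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GROUP_CASE,
    GROUP_CONTROL,
    InteractionEdge,
    LNC_MIR,
    MIR_MRNA,
    PPIEdge,
    write_expression_matrix,
    write_gmt,
    write_interaction_table,
    write_ppi_table,
    write_sample_metadata,
)

__all__ = [
    "SimulationConfig",
    "PlantedAxis",
    "GroundTruth",
    "SyntheticStudy",
    "generate_cohort_metadata",
    "generate_ground_truth",
    "generate_expression",
    "simulate_study",
    "write_study",
]

HOMO_SAPIENS = "Homo sapiens"

# Table-1 observed ranges used for the covariate columns.
AGE_RANGE = (25, 97)
PH_RANGE = (5.7, 6.9)
PMD_RANGE = (3.0, 30.0)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Counts describe the cohort and transcriptome; effect sizes are in log2
    units.  ``n_genes`` counts mRNAs; lncRNAs come on top of it.  The extra
    DE genes (not members of any axis) mirror the usual situation where
    most differential genes have no database-supported miRNA partner.
    """

    n_case: int = 25
    n_control: int = 25
    n_genes: int = 2000
    n_lncrna: int = 50
    n_mirna: int = 20
    n_axes: int = 10
    de_log2fc: float = 1.0
    axis_latent_sd: float = 1.0
    noise_sd: float = 0.3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    age_effect: float = 0.01
    gender_effect: float = 0.5
    frac_covariate_genes: float = 0.1
    n_extra_de_mrna: int = 173
    n_extra_de_lnc: int = 4
    n_decoy_interactions: int = 100
    n_decoy_ppi: int = 60
    n_gene_sets: int = 10
    gene_set_size: int = 30
    hard_decoys: bool = False
    seed: int = 0

    def __post_init__(self):
        positive = [
            "n_case",
            "n_control",
            "n_genes",
            "n_lncrna",
            "n_mirna",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.n_axes < 0:
            raise ValueError("n_axes must be >= 0")
        if self.n_axes > min(self.n_lncrna, self.n_mirna, self.n_genes):
            raise ValueError(
                "n_axes exceeds the available lncRNA/miRNA/mRNA symbols"
            )
        if self.n_axes + self.n_extra_de_mrna > self.n_genes:
            raise ValueError("planted DE mRNAs exceed n_genes")
        if self.n_axes + self.n_extra_de_lnc > self.n_lncrna:
            raise ValueError("planted DE lncRNAs exceed n_lncrna")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.axis_latent_sd < 0:
            raise ValueError("axis_latent_sd must be >= 0")
        if not (0.0 <= self.frac_covariate_genes <= 1.0):
            raise ValueError("frac_covariate_genes must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True, order=True)
class PlantedAxis:
    lncrna: str
    mirna: str
    mrna: str
    direction: str  # "up" or "down"


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery scoring."""

    planted_de: dict[str, str]  # symbol -> direction
    planted_axes: list[PlantedAxis]
    covariate_genes: set[str]
    enriched_set: str | None = None

    def validate(self, annotation: pd.DataFrame) -> None:
        symbols = set(annotation["symbol"])
        for ax in self.planted_axes:
            for sym in (ax.lncrna, ax.mrna):
                if sym not in symbols:
                    raise ConsistencyError(f"axis symbol {sym!r} not annotated")
                if self.planted_de.get(sym) != ax.direction:
                    raise ConsistencyError(
                        f"axis member {sym!r} missing from planted_de or with a "
                        f"discordant direction"
                    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_de": sorted(self.planted_de.items()),
            "planted_axes": [dataclasses.asdict(a) for a in self.planted_axes],
            "covariate_genes": sorted(self.covariate_genes),
            "enriched_set": self.enriched_set,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_de=dict(payload["planted_de"]),
            planted_axes=[PlantedAxis(**a) for a in payload["planted_axes"]],
            covariate_genes=set(payload["covariate_genes"]),
            enriched_set=payload.get("enriched_set"),
        )


@dataclass
class SyntheticStudy:
    """A complete generated study: inputs, files and the oracle."""

    config: SimulationConfig
    metadata: pd.DataFrame
    annotation: pd.DataFrame  # columns: symbol, biotype
    truth: GroundTruth
    expression: ExpressionMatrix  # linear scale
    lnc_mir: list[InteractionEdge]
    mir_mrna: list[InteractionEdge]
    ppi: list[PPIEdge]
    gene_sets: GeneSetCollection

    @property
    def lnc_symbols(self) -> set[str]:
        return set(self.annotation.loc[self.annotation["biotype"] == "lncRNA", "symbol"])


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------


def generate_cohort_metadata(n_case: int, n_control: int, seed: int) -> pd.DataFrame:
    """Sample a Table-1 shaped cohort: ages uniform over the observed 25-97
    range, gender Bernoulli(1/2), pH and post-mortem delay from plausible
    uniform ranges."""
    if n_case < 2 or n_control < 2:
        raise ValueError("each group needs at least 2 samples")
    rng = np.random.default_rng([seed, 0])
    n = n_case + n_control
    rows = []
    for i in range(n):
        is_case = i < n_case
        group = GROUP_CASE if is_case else GROUP_CONTROL
        rows.append(
            {
                "sample_id": f"SAMP{i + 1:03d}",
                "source_name": f"Brain BA10 post-mortem {group}",
                "group": group,
                "age": int(rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1)),
                "gender": "male" if rng.random() < 0.5 else "female",
                "ph": round(float(rng.uniform(*PH_RANGE)), 1),
                "pmd_hours": round(float(rng.uniform(*PMD_RANGE)), 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground truth + annotation + database files
# ---------------------------------------------------------------------------


def _symbols(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    mrnas = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    lncs = [f"LNC{i + 1:04d}" for i in range(config.n_lncrna)]
    mirs = [f"hsa-miR-{100 + i}-5p" for i in range(config.n_mirna)]
    return mrnas, lncs, mirs


def generate_ground_truth(
    config: SimulationConfig,
) -> tuple[
    GroundTruth,
    pd.DataFrame,
    list[InteractionEdge],
    list[InteractionEdge],
    list[PPIEdge],
    GeneSetCollection,
]:
    """Plant the axes and DE genes; emit annotation and database files.

    Returns (truth, annotation, lncRNA-miRNA edges, miRNA-mRNA edges, PPI
    edges, gene sets).  Every planted axis contributes its two database
    edges; decoy edges are confined to non-DE genes unless ``hard_decoys``.
    """
    rng = np.random.default_rng([config.seed, 1])
    mrnas, lncs, mirs = _symbols(config)
    mrna_perm = list(rng.permutation(mrnas))
    lnc_perm = list(rng.permutation(lncs))
    mir_perm = list(rng.permutation(mirs))

    axis_lncs = lnc_perm[: config.n_axes]
    axis_mrnas = mrna_perm[: config.n_axes]
    axis_mirs = [mir_perm[i % config.n_mirna] for i in range(config.n_axes)]
    directions = [("up", "down")[rng.integers(0, 2)] for _ in range(config.n_axes)]
    planted_axes = [
        PlantedAxis(l, m, g, d)
        for l, m, g, d in zip(axis_lncs, axis_mirs, axis_mrnas, directions)
    ]

    extra_de_mrnas = mrna_perm[config.n_axes : config.n_axes + config.n_extra_de_mrna]
    extra_de_lncs = lnc_perm[config.n_axes : config.n_axes + config.n_extra_de_lnc]
    planted_de: dict[str, str] = {}
    for ax in planted_axes:
        planted_de[ax.lncrna] = ax.direction
        planted_de[ax.mrna] = ax.direction
    for sym in [*extra_de_mrnas, *extra_de_lncs]:
        planted_de[sym] = ("up", "down")[rng.integers(0, 2)]

    non_de_mrnas = mrna_perm[config.n_axes + config.n_extra_de_mrna :]
    non_de_lncs = lnc_perm[config.n_axes + config.n_extra_de_lnc :]

    n_cov = int(round(config.frac_covariate_genes * (config.n_genes + config.n_lncrna)))
    cov_pool = [*non_de_mrnas, *non_de_lncs]
    n_cov = min(n_cov, len(cov_pool))
    covariate_genes = set(
        np.array(cov_pool)[rng.choice(len(cov_pool), size=n_cov, replace=False)]
    ) if n_cov else set()

    annotation = pd.DataFrame(
        {
            "symbol": mrnas + lncs,
            "biotype": ["mRNA"] * len(mrnas) + ["lncRNA"] * len(lncs),
        }
    )

    # --- interaction tables -------------------------------------------------
    lnc_mir: list[InteractionEdge] = []
    mir_mrna: list[InteractionEdge] = []
    for ax in planted_axes:
        lnc_mir.append(InteractionEdge(ax.lncrna, ax.mirna, LNC_MIR, HOMO_SAPIENS, "high"))
        mir_mrna.append(InteractionEdge(ax.mirna, ax.mrna, MIR_MRNA, HOMO_SAPIENS, "strong"))

    def _pick(pool: list[str]) -> str:
        return pool[int(rng.integers(0, len(pool)))]

    for _ in range(config.n_decoy_interactions):
        if non_de_lncs:
            lnc_mir.append(
                InteractionEdge(_pick(non_de_lncs), _pick(mirs), LNC_MIR, HOMO_SAPIENS, "high")
            )
        if non_de_mrnas:
            mir_mrna.append(
                InteractionEdge(_pick(mirs), _pick(non_de_mrnas), MIR_MRNA, HOMO_SAPIENS, "strong")
            )
    # edges the trust filters must discard: wrong species / low confidence / weak
    if non_de_lncs:
        lnc_mir.append(
            InteractionEdge(_pick(non_de_lncs), _pick(mirs), LNC_MIR, "Mus musculus", "high")
        )
        lnc_mir.append(
            InteractionEdge(_pick(non_de_lncs), _pick(mirs), LNC_MIR, HOMO_SAPIENS, "low")
        )
    if non_de_mrnas:
        mir_mrna.append(
            InteractionEdge(_pick(mirs), _pick(non_de_mrnas), MIR_MRNA, HOMO_SAPIENS, "weak")
        )
    if config.hard_decoys:
        # oppositely-regulated DE pairs: survive the DE gate, must die at the
        # sign (or correlation) gate
        ups = [s for s in [*extra_de_lncs] if planted_de[s] == "up"]
        downs = [s for s in [*extra_de_mrnas] if planted_de[s] == "down"]
        for l, g in zip(ups, downs):
            m = _pick(mirs)
            lnc_mir.append(InteractionEdge(l, m, LNC_MIR, HOMO_SAPIENS, "high"))
            mir_mrna.append(InteractionEdge(m, g, MIR_MRNA, HOMO_SAPIENS, "strong"))

    # --- PPI ----------------------------------------------------------------
    ppi: list[PPIEdge] = []
    seen_ppi: set[tuple[str, str]] = set()

    def _add_ppi(a: str, b: str, score: float) -> None:
        if a == b:
            return
        key = (min(a, b), max(a, b))
        if key in seen_ppi:
            return
        seen_ppi.add(key)
        ppi.append(PPIEdge(a, b, round(score, 3)))

    for a, b in zip(axis_mrnas, axis_mrnas[1:]):
        _add_ppi(a, b, float(rng.uniform(0.45, 0.95)))
    if len(axis_mrnas) >= 2:
        # one sub-threshold edge between axis mRNAs exercises the score gate
        _add_ppi(axis_mrnas[0], axis_mrnas[-1], float(rng.uniform(0.05, 0.35)))
    for _ in range(config.n_decoy_ppi):
        if len(non_de_mrnas) >= 2:
            _add_ppi(_pick(non_de_mrnas), _pick(non_de_mrnas), float(rng.uniform(0.05, 0.95)))

    # --- gene sets ----------------------------------------------------------
    sets = []
    enriched_name = None
    if config.n_gene_sets > 0:
        fill = [s for s in non_de_mrnas]
        enriched_name = "PW_0001_planted"
        n_fill = max(config.gene_set_size - len(axis_mrnas), 0)
        fill_genes = list(
            np.array(fill)[rng.choice(len(fill), size=min(n_fill, len(fill)), replace=False)]
        )
        sets.append(
            GeneSet(
                enriched_name,
                "synthetic pathway enriched for planted axis mRNAs",
                tuple(sorted(set(axis_mrnas) | set(fill_genes)) or ["EMPTY"]),
            )
        )
        for i in range(1, config.n_gene_sets):
            members = np.array(fill)[
                rng.choice(len(fill), size=min(config.gene_set_size, len(fill)), replace=False)
            ]
            sets.append(
                GeneSet(f"PW_{i + 1:04d}", "synthetic background pathway", tuple(sorted(members)))
            )
    gene_sets = GeneSetCollection(sets)

    truth = GroundTruth(
        planted_de=planted_de,
        planted_axes=planted_axes,
        covariate_genes=covariate_genes,
        enriched_set=enriched_name,
    )
    truth.validate(annotation)
    return truth, annotation, lnc_mir, mir_mrna, ppi, gene_sets


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    truth: GroundTruth,
    annotation: pd.DataFrame,
    metadata: pd.DataFrame,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Simulate the linear-scale expression matrix from the planted truth.

    See the module docstring for the signal model.  Strictly positive by
    construction (the matrix is 2^log2-signal).
    """
    truth.validate(annotation)
    if len(metadata) != config.n_case + config.n_control:
        raise ConsistencyError("metadata row count does not match the config cohort")
    rng = np.random.default_rng([config.seed, 2])
    symbols = list(annotation["symbol"])
    sym_index = {s: i for i, s in enumerate(symbols)}
    for sym in truth.planted_de:
        if sym not in sym_index:
            raise ConsistencyError(f"planted symbol {sym!r} absent from annotation")
    n_genes = len(symbols)
    n_samples = len(metadata)
    case = (metadata["group"] == GROUP_CASE).to_numpy(dtype=float)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    # planted genes sit in the upper expression range: detected transcripts
    # on arrays are well expressed, and the filters are meant to act on the
    # background, not on the truth
    for sym in truth.planted_de:
        baseline[sym_index[sym]] = rng.normal(config.baseline_log2_mean + 1.0, 0.5)

    signal = np.tile(baseline[:, None], (1, n_samples))

    for sym, direction in truth.planted_de.items():
        beta = config.de_log2fc if direction == "up" else -config.de_log2fc
        signal[sym_index[sym], :] += beta * case

    for ax in truth.planted_axes:
        f = rng.normal(0.0, config.axis_latent_sd, n_samples)
        signal[sym_index[ax.lncrna], :] += f
        signal[sym_index[ax.mrna], :] += f

    if truth.covariate_genes:
        age = metadata["age"].to_numpy(dtype=float)
        age_c = age - age.mean()
        female = (metadata["gender"] == "female").to_numpy(dtype=float)
        for sym in truth.covariate_genes:
            signal[sym_index[sym], :] += (
                config.age_effect * age_c + config.gender_effect * female
            )

    signal += rng.normal(0.0, config.noise_sd, (n_genes, n_samples))

    data = pd.DataFrame(
        np.exp2(signal), index=pd.Index(symbols, name="symbol"),
        columns=list(metadata["sample_id"]),
    )
    return ExpressionMatrix(data, "linear")


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full study: metadata, truth, files and expression."""
    metadata = generate_cohort_metadata(config.n_case, config.n_control, config.seed)
    truth, annotation, lnc_mir, mir_mrna, ppi, gene_sets = generate_ground_truth(config)
    expression = generate_expression(truth, annotation, metadata, config)
    return SyntheticStudy(
        config=config,
        metadata=metadata,
        annotation=annotation,
        truth=truth,
        expression=expression,
        lnc_mir=lnc_mir,
        mir_mrna=mir_mrna,
        ppi=ppi,
        gene_sets=gene_sets,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every study file; byte-identical for identical (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "annotation.tsv",
        "lncrna_list": outdir / "lncrna_list.tsv",
        "lnc_mir": outdir / "lncrna_mirna.tsv",
        "mir_mrna": outdir / "mirna_mrna.tsv",
        "ppi": outdir / "ppi.tsv",
        "gmt": outdir / "pathways.gmt",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "sim_config.json",
    }
    write_expression_matrix(study.expression, paths["expression"])
    write_sample_metadata(study.metadata, paths["metadata"])
    study.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    lnc_list = sorted(study.lnc_symbols)
    paths["lncrna_list"].write_text("symbol\n" + "\n".join(lnc_list) + "\n")
    write_interaction_table(study.lnc_mir, LNC_MIR, paths["lnc_mir"])
    write_interaction_table(study.mir_mrna, MIR_MRNA, paths["mir_mrna"])
    write_ppi_table(study.ppi, paths["ppi"])
    write_gmt(study.gene_sets, paths["gmt"])
    study.truth.to_json(paths["ground_truth"])
    paths["config"].write_text(json.dumps(study.config.to_dict(), indent=1) + "\n")
    return paths
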