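"""Planted-truth simulator for the CT screening pipeline.

The generator emulates the structure of the real compendium: a few testis /
germ-cell TARGET groups, ~45 normal somatic tissue groups, and a set of
cancer subtypes each matched to a tissue of origin, with replicate arrays
per group. Expression is modeled on the log2 scale with three tiers:

* a background tier (mean 4.5) for silent (probeset, group) pairs,
* a mid "expressed" tier (mean 6.25, between the intended BEC of 5.5 and
  the intended upper quartile of 6.9) used for the target signal of
  planted SET/PET genes,
* a high tier (mean 7.5, above the upper quartile) for SEHET/PEHET
  targets, UE/IE expression and cancer derepression.

Each probeset draws one level per tier (per-probe affinity jitter) shared
across all groups in that tier; samples add i.i.d. Gaussian measurement
noise. Planted classes realize their defining pattern exactly at the mean
level: e.g. a planted PET gene has 1-3 somatic exception tissues at its
target tier, and a derepressed (gene, subtype) pair puts the cancer group
in the high tier while its matched normal stays at background.

Because only a minority of planted cells are expressed, the pooled
quartiles of a simulated matrix fall inside the background mode and are
not meaningful detection cutoffs; the generator therefore states the tier
boundaries it is built around (BEC 5.5, quartiles 4.4/6.9) and analyses of
simulated data pin the global thresholds to them (see
:meth:`SimulationConfig.intended_thresholds`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError
from .model import (
    CANCER,
    NORMAL,
    TARGET,
    ExpressionMatrix,
    GlobalThresholds,
    ProbesetAnnotation,
    SampleAnnotation,
)
from .tissue import SE_CLASSES, TESTIS_CLASSES

#: planted tissue classes, in generation order
PLANTED_CLASSES = ("SET", "SEHET", "PET", "PEHET", "IE", "UE", "BACKGROUND")

#: tier used for the target-compartment signal of each CT class
_TARGET_TIER = {"SET": "mid", "SEHET": "high", "PET": "mid", "PEHET": "high"}


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the simulator.

    Planted gene counts and the group structure follow the compendium the
    screen was designed for; tier means sit >= 3 sigma from every decision
    boundary so that planted memberships are recoverable (the regime the
    fixed thresholds assume). ``background_sd``/``mid_sd``/``expressed_sd``
    are per-probeset level (probe-affinity) jitters; ``noise_sd`` is the
    per-sample measurement noise.
    """

    n_normal_tissues: int = 45
    n_target_groups: int = 4
    n_cancer_subtypes: int = 10
    samples_per_group: int = 3
    target_samples_per_group: int = 2

    background_mean: float = 4.5
    background_sd: float = 0.15
    mid_mean: float = 6.25
    mid_sd: float = 0.1
    expressed_mean: float = 7.5
    expressed_sd: float = 0.2
    noise_sd: float = 0.3

    n_set: int = 50
    n_sehet: int = 50
    n_pet: int = 30
    n_pehet: int = 30
    n_ie: int = 40
    n_ue: int = 60
    n_background: int = 240
    n_unmapped_probesets: int = 5

    probesets_per_gene: tuple[int, int] = (1, 3)
    derepression_prob: float = 0.3
    pet_exception_range: tuple[int, int] = (1, 3)
    ie_detected_range: tuple[int, int] = (4, 10)

    bec: float = 5.5
    q_low: float = 4.4
    q_high: float = 6.9

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.expressed_mean > self.background_mean:
            raise ConfigError("expressed_mean must exceed background_mean")
        if not self.background_mean < self.mid_mean < self.expressed_mean:
            raise ConfigError("mid_mean must lie between the background and expressed means")
        for name in ("background_sd", "mid_sd", "expressed_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("n_set", "n_sehet", "n_pet", "n_pehet", "n_ie", "n_ue",
                     "n_background", "n_unmapped_probesets"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_normal_tissues < 1 or self.n_target_groups < 1:
            raise ConfigError("need at least one NORMAL and one TARGET group")
        if not (0 <= self.derepression_prob <= 1):
            raise ConfigError("derepression_prob must be in [0, 1]")
        lo, hi = self.probesets_per_gene
        if not (1 <= lo <= hi):
            raise ConfigError("probesets_per_gene must satisfy 1 <= lo <= hi")
        lo, hi = self.ie_detected_range
        if not (1 <= lo <= hi <= self.n_normal_tissues):
            raise ConfigError("ie_detected_range must fit inside the somatic tissues")
        lo, hi = self.pet_exception_range
        if not (1 <= lo <= hi <= self.n_normal_tissues):
            raise ConfigError("pet_exception_range must fit inside the somatic tissues")

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "SET": self.n_set, "SEHET": self.n_sehet, "PET": self.n_pet,
            "PEHET": self.n_pehet, "IE": self.n_ie, "UE": self.n_ue,
            "BACKGROUND": self.n_background,
        }

    def intended_thresholds(self) -> GlobalThresholds:
        """Tier boundaries the noise model is built around (pin these when
        classifying simulated data)."""
        return GlobalThresholds(bec=self.bec, q_low=self.q_low, q_high=self.q_high)

    def to_kv(self) -> str:
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{k}={v}")
        return "\n".join(lines) + "\n"


@dataclass
class TruthTable:
    """Planted memberships emitted alongside the dataset.

    ``genes``: one row per planted gene (index gene_symbol) with columns
    intended_class, probesets (';'-joined), derepressed_subtypes
    (';'-joined), intended_any_ucndh, intended_ct_candidate,
    intended_core_ct. ``probesets``: one row per probeset (index
    probeset_id) with gene_symbol and intended_class.
    """

    genes: pd.DataFrame
    probesets: pd.DataFrame

    def write(self, gene_path, probeset_path) -> None:
        out = self.genes.copy()
        for c in ("intended_any_ucndh", "intended_ct_candidate", "intended_core_ct"):
            out[c] = out[c].astype(int)
        out.rename_axis("gene_symbol").to_csv(gene_path, sep="\t")
        self.probesets.rename_axis("probeset_id").to_csv(probeset_path, sep="\t")


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    samples: SampleAnnotation
    probesets: ProbesetAnnotation
    truth: TruthTable
    config: SimulationConfig


def _build_groups(config: SimulationConfig, rng: np.random.Generator):
    groups = {}
    normals = [f"tissue_{i + 1:02d}" for i in range(config.n_normal_tissues)]
    for g in normals:
        groups[g] = (NORMAL, "", f"normal somatic {g}")
    for i in range(config.n_target_groups):
        g = f"target_{i + 1:02d}"
        groups[g] = (TARGET, "", "testis/germ-cell compartment")
    origins = rng.choice(config.n_normal_tissues, size=config.n_cancer_subtypes, replace=True)
    cancers = []
    for i, o in enumerate(origins):
        g = f"cancer_{i + 1:02d}"
        groups[g] = (CANCER, normals[o], f"cancer subtype of {normals[o]}")
        cancers.append(g)
    gdf = pd.DataFrame(
        [(g, cat, mn, lab) for g, (cat, mn, lab) in groups.items()],
        columns=["group_id", "category", "matched_normal", "label"],
    ).set_index("group_id")
    rows = []
    for g, (cat, _, _) in groups.items():
        n = config.target_samples_per_group if cat == TARGET else config.samples_per_group
        for j in range(n):
            rows.append((f"{g}_s{j + 1}", g))
    sdf = pd.DataFrame(rows, columns=["sample_id", "group_id"]).set_index("sample_id")
    return sdf, gdf, normals, cancers


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset; identical config (including seed) => identical output."""
    rng = np.random.default_rng(config.seed)
    sdf, gdf, normals, cancers = _build_groups(config, rng)
    annot = SampleAnnotation(samples=sdf, groups=gdf)
    target_groups = annot.groups_of(TARGET)
    group_ids = list(gdf.index)
    group_pos = {g: i for i, g in enumerate(group_ids)}
    matched = {cg: annot.matched_normal(cg) for cg in cancers}

    lo_pp, hi_pp = config.probesets_per_gene
    ie_lo, ie_hi = config.ie_detected_range
    pe_lo, pe_hi = config.pet_exception_range

    gene_rows, probe_rows = [], []
    probe_ids, gene_of_probe = [], []
    # per-probeset tier assignment matrix: 0 background, 1 mid, 2 high
    tier_rows = []

    gene_counter = 0
    for cls in PLANTED_CLASSES:
        for _ in range(config.class_counts[cls]):
            gene_counter += 1
            symbol = f"G{gene_counter:04d}_{cls}"
            n_probes = int(rng.integers(lo_pp, hi_pp + 1))
            probes = [f"{symbol}_at{j + 1}" for j in range(n_probes)]

            tier = np.zeros(len(group_ids), dtype=int)
            exception_tissues: list[str] = []
            if cls in TESTIS_CLASSES:
                t = 1 if _TARGET_TIER[cls] == "mid" else 2
                for g in target_groups:
                    tier[group_pos[g]] = t
                if cls in ("PET", "PEHET"):
                    k = int(rng.integers(pe_lo, pe_hi + 1))
                    exception_tissues = list(
                        rng.choice(normals, size=k, replace=False)
                    )
                    for g in exception_tissues:
                        tier[group_pos[g]] = t
            elif cls == "IE":
                k = int(rng.integers(ie_lo, ie_hi + 1))
                for g in rng.choice(normals, size=k, replace=False):
                    tier[group_pos[g]] = 2
            elif cls == "UE":
                tier[:] = 2

            derepressed: list[str] = []
            if cls in TESTIS_CLASSES and config.derepression_prob > 0:
                for cg in cancers:
                    if matched[cg] in exception_tissues:
                        continue  # tissue of origin expresses the gene: no UCNDH
                    if rng.random() < config.derepression_prob:
                        derepressed.append(cg)
                        tier[group_pos[cg]] = 2

            any_ucndh = bool(derepressed)
            gene_rows.append(
                {
                    "gene_symbol": symbol,
                    "intended_class": cls,
                    "probesets": ";".join(probes),
                    "derepressed_subtypes": ";".join(derepressed),
                    "intended_any_ucndh": any_ucndh,
                    "intended_ct_candidate": any_ucndh and cls in TESTIS_CLASSES,
                    "intended_core_ct": any_ucndh and cls in SE_CLASSES,
                }
            )
            for p in probes:
                probe_ids.append(p)
                gene_of_probe.append(symbol)
                probe_rows.append({"probeset_id": p, "gene_symbol": symbol,
                                   "intended_class": cls})
                tier_rows.append(tier.copy())

    for j in range(config.n_unmapped_probesets):
        p = f"UNMAPPED_at{j + 1}"
        probe_ids.append(p)
        gene_of_probe.append("")
        probe_rows.append({"probeset_id": p, "gene_symbol": "", "intended_class": "BACKGROUND"})
        tier_rows.append(np.zeros(len(group_ids), dtype=int))

    tiers = np.asarray(tier_rows)  # probesets x groups
    n_probesets = len(probe_ids)

    # per-probeset tier levels (probe-affinity jitter, shared across groups)
    levels = np.empty((n_probesets, 3))
    levels[:, 0] = rng.normal(config.background_mean, config.background_sd, n_probesets)
    levels[:, 1] = rng.normal(config.mid_mean, config.mid_sd, n_probesets)
    levels[:, 2] = rng.normal(config.expressed_mean, config.expressed_sd, n_probesets)
    group_means = np.take_along_axis(levels, tiers, axis=1)  # probesets x groups

    sample_group_pos = np.array([group_pos[g] for g in sdf["group_id"]])
    values = group_means[:, sample_group_pos] + rng.normal(
        0.0, config.noise_sd, size=(n_probesets, len(sdf))
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(np.round(values, 4), index=probe_ids, columns=sdf.index)
    )
    probesets = ProbesetAnnotation(
        pd.Series(gene_of_probe, index=pd.Index(probe_ids, name="probeset_id"),
                  name="gene_symbol")
    )
    truth = TruthTable(
        genes=pd.DataFrame(gene_rows).set_index("gene_symbol"),
        probesets=pd.DataFrame(probe_rows).set_index("probeset_id"),
    )
    return SimulatedDataset(matrix=matrix, samples=annot, probesets=probesets,
                            truth=truth, config=config)


@dataclass
class RecoverySummary:
    """Per-class recovery of planted memberships.

    ``tissue_probeset``/``tissue_gene``: per intended class, counts,
    sensitivity and precision (gene level uses the any-probeset rule).
    ``confusion``: intended x called probeset-level matrix. ``ct_genes``:
    sensitivity/precision of gene-level CT-candidate and core-CT calls,
    plus the number of planted-UE genes called CT candidate.
    """

    tissue_probeset: pd.DataFrame
    tissue_gene: pd.DataFrame
    confusion: pd.DataFrame
    ct_genes: dict = field(default_factory=dict)


def _per_class_stats(intended: pd.Series, called: pd.Series) -> pd.DataFrame:
    classes = sorted(set(intended) | set(called))
    rows = []
    for cls in classes:
        planted = intended == cls
        hit = planted & (called == cls)
        pos = called == cls
        rows.append(
            {
                "class": cls,
                "n_planted": int(planted.sum()),
                "n_called": int(pos.sum()),
                "sensitivity": hit.sum() / planted.sum() if planted.any() else np.nan,
                "precision": (hit.sum() / pos.sum()) if pos.any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def evaluate_recovery(truth: TruthTable, tissue_records: pd.DataFrame,
                      calls=None) -> RecoverySummary:
    """Score classification output against the planted truth.

    ``tissue_records`` is the tissue classifier output; ``calls`` (optional)
    the :class:`~ctscreen.calls.CTCallTable` for CT-level scoring. Planted
    BACKGROUND genes are expected to classify as OTHER.
    """
    tp = truth.probesets
    missing = tp.index.difference(tissue_records.index)
    if len(missing):
        raise ConsistencyError(f"calls are missing {len(missing)} planted probeset(s)")
    expected = tp["intended_class"].replace({"BACKGROUND": "OTHER"})
    called = tissue_records["class_label"].reindex(tp.index)
    confusion = pd.crosstab(expected, called, rownames=["intended"], colnames=["called"])
    probeset_stats = _per_class_stats(expected, called)

    # gene level: a gene counts as class C if any of its probesets is called C
    mapped = tp[tp["gene_symbol"] != ""]
    gene_called = {}
    for cls in set(called):
        hit = called.loc[mapped.index] == cls
        gene_called[cls] = set(mapped.loc[hit[hit].index, "gene_symbol"])
    gene_intended = truth.genes["intended_class"].replace({"BACKGROUND": "OTHER"})
    rows = []
    for cls in sorted(set(gene_intended) | set(gene_called)):
        planted = set(gene_intended.index[gene_intended == cls])
        pos = gene_called.get(cls, set())
        hit = planted & pos
        rows.append(
            {
                "class": cls,
                "n_planted": len(planted),
                "n_called": len(pos),
                "sensitivity": len(hit) / len(planted) if planted else np.nan,
                "precision": len(hit) / len(pos) if pos else np.nan,
            }
        )
    gene_stats = pd.DataFrame(rows).set_index("class")

    ct = {}
    if calls is not None:
        tg = truth.genes
        called_genes = calls.genes
        for flag, intended_col in (("ct_candidate", "intended_ct_candidate"),
                                   ("core_ct", "intended_core_ct")):
            planted = set(tg.index[tg[intended_col]])
            pos = set(called_genes.index[called_genes[flag]])
            hit = planted & pos
            ct[f"{flag}_sensitivity"] = len(hit) / len(planted) if planted else np.nan
            ct[f"{flag}_precision"] = len(hit) / len(pos) if pos else np.nan
            ct[f"{flag}_n_planted"] = len(planted)
            ct[f"{flag}_n_called"] = len(pos)
        ue_genes = set(tg.index[tg["intended_class"] == "UE"])
        ct["ue_called_ct_candidate"] = len(
            ue_genes & set(called_genes.index[called_genes["ct_candidate"]])
        )
    return RecoverySummary(tissue_probeset=probeset_stats, tissue_gene=gene_stats,
                           confusion=confusion, ct_genes=ct)
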