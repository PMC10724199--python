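"""Synthetic bulk RNA-seq generator with planted ground truth.

Emulates the study design — three donor groups (healthy plus two patient
groups with disease-activity scores), four sorted cell types, three
conditions (steady state, anti-CD3 stimulation, PBS control) — and plants:

* a shared stimulation-response program in all stimulated samples,
* group-specific differentially responding genes (aCD3 vs PBS contrast),
* an interferon-response set whose steady-state shift follows the donor's
  activity class,
* co-regulated gene modules with distinct stratum profiles,
* stratum-specific co-expression partners of interferon genes,
* ligand-receptor co-regulation events with group-wise detection
  probabilities.

Counts are generated as log-normal expected FPKM scaled by gene length and
sequencing depth, then Poisson-rounded, so FPKM normalization inverts the
scaling in expectation.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from stimprofiler import matrix as mx
from stimprofiler.genesets import GeneSetCatalog, classify_activity, write_gmt

LR_CATEGORIES = ("Cytokines", "TGF", "TNF", "chemokines", "growth factor", "others")


@dataclass
class LREventSpec:
    """A planted ligand-receptor co-regulation event.

    ``detect_prob`` maps donor group to the probability that the event is
    planted in a given donor (ligand strongly up-regulated in the sender's
    stimulated sample).  Missing groups default to 0.
    """

    sender: str = "Th"
    receiver: str = "B"
    detect_prob: dict[str, float] = field(default_factory=dict)
    ligand: str | None = None
    receptor: str | None = None
    category: str = "Cytokines"


def default_lr_events() -> list[LREventSpec]:
    return [
        LREventSpec("Th", "B", {"HD": 0.3, "pSS": 0.6, "SLE": 0.9}),
        LREventSpec("CTL", "NK", {"HD": 0.2, "pSS": 0.7, "SLE": 0.7}),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the simulator; defaults mirror the emulated cohort."""

    n_genes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HD": 24, "pSS": 23, "SLE": 25}
    )
    cell_types: tuple[str, ...] = mx.CELL_TYPES
    conditions: tuple[str, ...] = mx.CONDITIONS
    n_deg: int = 100
    deg_log2fc: float = 1.5
    n_stim_genes: int = 100
    stim_log2fc: float = 2.0
    ifn_set_size: int = 50
    activity_effect: dict[str, float] = field(
        default_factory=lambda: {"Low": 0.5, "Moderate": 1.0, "High": 2.0}
    )
    n_modules: int = 4
    module_sizes: tuple[int, ...] = (60, 60, 60, 60)
    module_sep: float = 3.0
    n_coexpr: int = 0
    coexpr_rho: float = 0.9
    coexpr_stratum: tuple[str, str] = ("Th", "SLE")
    n_markers: int = 25
    marker_log2fc: float = 3.0
    lr_events: list[LREventSpec] = field(default_factory=default_lr_events)
    lr_log2fc: float = 8.0
    dispersion: float = 0.5
    donor_sd: float = 0.3
    dropout_rate: float = 0.0
    qc_dropout: float = 0.0
    base_log2_fpkm_mean: float = 3.5
    base_log2_fpkm_sd: float = 1.5
    planted_log2_fpkm: float = 6.0
    depth: float = 5e6
    high_cutoff: int = 8
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(n < 0 for n in self.group_sizes.values()) or sum(
            self.group_sizes.values()
        ) <= 0:
            raise ValueError("group sizes must be non-negative with a positive total")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0 <= self.qc_dropout < 1:
            raise ValueError("qc_dropout must lie in [0, 1)")
        if not np.isfinite(self.deg_log2fc):
            raise ValueError("deg_log2fc must be finite")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if not 0 <= self.coexpr_rho < 1:
            raise ValueError("coexpr_rho must lie in [0, 1)")
        n_patient_groups = sum(
            1 for g, n in self.group_sizes.items() if g != "HD" and n > 0
        )
        reserved = (
            self.ifn_set_size
            + self.n_stim_genes
            + self.n_deg * n_patient_groups
            + sum(self.module_sizes)
            + self.n_coexpr
            + self.n_markers * len(self.cell_types)
            + 2 * len(self.lr_events)
        )
        if reserved > self.n_genes:
            raise ValueError(
                f"inconsistent config: planted sets need {reserved} genes "
                f"but n_genes={self.n_genes}"
            )


@dataclass
class TruthSet:
    """All planted structure, for downstream recovery tests.

    ``expected_fpkm`` carries the latent (pre-Poisson) FPKM matrix; it is
    not serialized to JSON.
    """

    genes: list[str]
    deg_genes: dict[str, dict[str, float]]
    stim_genes: dict[str, float]
    ifn_genes: list[str]
    coexpr_partners: dict[str, dict]
    module_assignment: dict[str, int]
    marker_genes: dict[str, list[str]]
    lr_events: list[dict]
    activity_scores: dict[str, int]
    activity_classes: dict[str, str]
    expected_fpkm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        universe = set(self.genes)
        planted = set(self.ifn_genes) | set(self.stim_genes) | set(
            self.module_assignment
        ) | set(self.coexpr_partners)
        for mapping in self.deg_genes.values():
            planted |= set(mapping)
        for genes in self.marker_genes.values():
            planted |= set(genes)
        for event in self.lr_events:
            planted |= {event["ligand"], event["receptor"]}
        missing = planted - universe
        if missing:
            raise ValueError(f"planted genes outside the universe: {sorted(missing)[:5]}")

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload.pop("expected_fpkm")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(expected_fpkm=None, **payload)


def _allocate_genes(config: SimulationConfig) -> dict:
    """Deterministic, disjoint allocation of planted gene identities."""
    patient_groups = [g for g, n in config.group_sizes.items() if g != "HD" and n > 0]
    ifn = [f"IFNSIM{i:04d}" for i in range(1, config.ifn_set_size + 1)]
    ligands = [f"LIGSIM{i:02d}" for i in range(1, len(config.lr_events) + 1)]
    receptors = [f"RECSIM{i:02d}" for i in range(1, len(config.lr_events) + 1)]
    n_special = len(ifn) + len(ligands) + len(receptors)
    n_generic = config.n_genes - n_special
    generic = [f"GENE{i:04d}" for i in range(1, n_generic + 1)]
    pool = iter(generic)

    def take(n: int) -> list[str]:
        return [next(pool) for _ in range(n)]

    alloc = {
        "ifn": ifn,
        "ligands": ligands,
        "receptors": receptors,
        "stim": take(config.n_stim_genes),
        "deg": {g: take(config.n_deg) for g in patient_groups},
        "modules": [take(n) for n in config.module_sizes],
        "coexpr": take(config.n_coexpr),
        "markers": {ct: take(config.n_markers) for ct in config.cell_types},
        "rest": list(pool),
    }
    genes = ifn + ligands + receptors + generic
    alloc["all"] = genes
    return alloc


def _draw_activity(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, str], list[str]]:
    """Donor ids plus activity scores/classes (patients only).

    Scores are integers 0-14; for each patient group the draw is repeated
    until all three classes are populated (when the group has >= 3 donors).
    """
    donors: list[str] = []
    scores: dict[str, int] = {}
    classes: dict[str, str] = {}
    for group in config.group_sizes:
        n = config.group_sizes[group]
        ids = [f"{group}{i:02d}" for i in range(1, n + 1)]
        donors.extend(ids)
        if group == "HD" or n == 0:
            continue
        for _ in range(200):
            drawn = rng.integers(0, 15, size=n)
            cls = [classify_activity(s, config.high_cutoff)[0] for s in drawn]
            if n < 3 or len(set(cls)) == 3:
                break
        for donor, s, c in zip(ids, drawn, cls):
            scores[donor] = int(s)
            classes[donor] = c
    return scores, classes, donors


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[mx.ExpressionMatrix, dict[str, float], pd.DataFrame, TruthSet]:
    """Generate (raw counts, gene lengths, sample table, truth set)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    alloc = _allocate_genes(config)
    genes = alloc["all"]
    gene_index = {g: i for i, g in enumerate(genes)}

    scores, classes, donors = _draw_activity(config, rng)
    donor_group = {d: g for g in config.group_sizes for d in donors if d.startswith(g)}

    # sample table for the full grid, then seed-driven QC attrition
    rows = []
    for donor in donors:
        for ct in config.cell_types:
            for cond in config.conditions:
                rows.append(
                    (
                        f"{donor}_{ct}_{cond}",
                        donor,
                        donor_group[donor],
                        ct,
                        cond,
                        scores.get(donor, np.nan),
                        classes.get(donor, ""),
                        "",
                    )
                )
    samples = pd.DataFrame(rows, columns=list(mx.SAMPLE_COLUMNS))
    if config.qc_dropout > 0:
        n_drop = int(np.floor(config.qc_dropout * len(samples)))
        drop_idx = rng.choice(len(samples), size=n_drop, replace=False)
        samples = samples.drop(index=drop_idx).reset_index(drop=True)
    samples = mx.validate_samples(samples)

    n_genes, n_samples = len(genes), len(samples)
    lengths = rng.integers(300, 5001, size=n_genes).astype(float)
    gene_lengths = dict(zip(genes, lengths))

    mu = rng.normal(config.base_log2_fpkm_mean, config.base_log2_fpkm_sd, size=n_genes)
    planted_hi = alloc["ifn"] + alloc["receptors"] + alloc["coexpr"]
    for g in planted_hi:
        mu[gene_index[g]] = rng.normal(config.planted_log2_fpkm, 0.5)
    # ligands start at modest expression: high enough that Poisson spikes in
    # the control sample do not mimic up-regulation, low enough that a
    # planted boost stays compositionally negligible (FPKM is a relative
    # measure: one huge gene deflates all others)
    for g in alloc["ligands"]:
        mu[gene_index[g]] = rng.normal(2.0, 0.5)

    donor_idx = {d: i for i, d in enumerate(donors)}
    donor_effect = rng.normal(0.0, config.donor_sd, size=(n_genes, len(donors)))

    sample_donor = samples["donor_id"].map(donor_idx).to_numpy()
    sample_group = samples["group"].to_numpy()
    sample_ct = samples["cell_type"].to_numpy()
    sample_cond = samples["condition"].to_numpy()
    sample_class = samples["activity_class"].to_numpy()

    effects = np.zeros((n_genes, n_samples))
    is_acd3 = sample_cond == "aCD3"
    is_steady = sample_cond == "steady"

    # shared stimulation program (all groups)
    stim_sign = np.where(np.arange(config.n_stim_genes) % 5 == 4, -1.0, 1.0)
    stim_genes = dict(zip(alloc["stim"], stim_sign * config.stim_log2fc))
    for g, lfc in stim_genes.items():
        effects[gene_index[g], is_acd3] += lfc

    # group-specific differential response to stimulation
    deg_truth: dict[str, dict[str, float]] = {}
    for group, deg_list in alloc["deg"].items():
        signs = np.where(np.arange(len(deg_list)) % 2 == 0, 1.0, -1.0)
        deg_truth[group] = dict(zip(deg_list, signs * config.deg_log2fc))
        cols = is_acd3 & (sample_group == group)
        for g, lfc in deg_truth[group].items():
            effects[gene_index[g], cols] += lfc

    # interferon shift at steady state, scaled by activity class
    ifn_rows = [gene_index[g] for g in alloc["ifn"]]
    for cls, shift in config.activity_effect.items():
        cols = is_steady & (sample_class == cls)
        if cols.any() and shift:
            effects[np.ix_(ifn_rows, cols)] += shift

    # co-regulated modules: distinct profile per (cell type, condition)
    module_truth: dict[str, int] = {}
    for m, module in enumerate(alloc["modules"]):
        profile = {
            (ct, cond): rng.normal(0.0, config.module_sep)
            for ct in config.cell_types
            for cond in config.conditions
        }
        rows_m = [gene_index[g] for g in module]
        for (ct, cond), offset in profile.items():
            cols = (sample_ct == ct) & (sample_cond == cond)
            if cols.any():
                effects[np.ix_(rows_m, cols)] += offset
        for g in module:
            module_truth[g] = m

    # ligand-receptor events, planted per donor
    lr_truth: list[dict] = []
    for k, event in enumerate(config.lr_events):
        ligand = event.ligand or alloc["ligands"][k]
        receptor = event.receptor or alloc["receptors"][k]
        planted: dict[str, bool] = {}
        for donor in donors:
            prob = event.detect_prob.get(donor_group[donor], 0.0)
            flag = bool(rng.random() < prob)
            planted[donor] = flag
            if flag:
                cols = (
                    (samples["donor_id"] == donor).to_numpy()
                    & is_acd3
                    & (sample_ct == event.sender)
                )
                effects[gene_index[ligand], cols] += config.lr_log2fc
        lr_truth.append(
            {
                "sender": event.sender,
                "receiver": event.receiver,
                "ligand": ligand,
                "receptor": receptor,
                "category": event.category,
                "detect_prob": dict(event.detect_prob),
                "planted": planted,
            }
        )

    noise = rng.normal(0.0, config.dispersion, size=(n_genes, n_samples))
    latent = mu[:, None] + donor_effect[:, sample_donor] + effects + noise

    # stratum-specific co-expression partners of interferon genes
    coexpr_truth: dict[str, dict] = {}
    if alloc["coexpr"]:
        ct0, grp0 = config.coexpr_stratum
        cols = is_steady & (sample_ct == ct0) & (sample_group == grp0)
        base_sd = float(np.hypot(config.donor_sd, config.dispersion))
        for j, partner in enumerate(alloc["coexpr"]):
            target = alloc["ifn"][j % len(alloc["ifn"])]
            gi, pi = gene_index[target], gene_index[partner]
            deviation = latent[gi, cols] - mu[gi]
            own = rng.normal(0.0, base_sd, size=cols.sum())
            # match the target's baseline level inside the stratum: Euclidean
            # distance is level-sensitive, so co-expression means "similar
            # values", not just a correlated shape
            latent[pi, cols] = (
                mu[gi]
                + config.coexpr_rho * deviation
                + np.sqrt(1 - config.coexpr_rho**2) * own
            )
            coexpr_truth[partner] = {
                "ifn_gene": target,
                "rho": config.coexpr_rho,
                "stratum": [ct0, grp0],
            }

    expected_fpkm = np.exp2(latent)
    if config.dropout_rate > 0:
        mask = rng.random(size=expected_fpkm.shape) < config.dropout_rate
        expected_fpkm = np.where(mask, 0.0, expected_fpkm)

    lam = expected_fpkm * (lengths[:, None] / 1000.0) * (config.depth / 1e6)
    counts = rng.poisson(lam).astype(np.int64)

    truth = TruthSet(
        genes=genes,
        deg_genes=deg_truth,
        stim_genes=stim_genes,
        ifn_genes=alloc["ifn"],
        coexpr_partners=coexpr_truth,
        module_assignment=module_truth,
        marker_genes={ct: list(g) for ct, g in alloc["markers"].items()},
        lr_events=lr_truth,
        activity_scores=scores,
        activity_classes=classes,
        expected_fpkm=pd.DataFrame(
            np.exp2(latent), index=genes, columns=samples["sample_id"]
        ),
    )

    # marker genes: elevated in their own cell type (all conditions)
    for ct, marker_list in alloc["markers"].items():
        rows_m = [gene_index[g] for g in marker_list]
        cols = sample_ct == ct
        if cols.any():
            add = config.marker_log2fc
            counts_boost = expected_fpkm[np.ix_(rows_m, np.where(cols)[0])]
            # apply marker boost on the latent scale and re-draw those counts
            boosted = counts_boost * (2.0**add)
            lam_m = (
                boosted
                * (lengths[rows_m, None] / 1000.0)
                * (config.depth / 1e6)
            )
            counts[np.ix_(rows_m, np.where(cols)[0])] = rng.poisson(lam_m)
            truth.expected_fpkm.iloc[rows_m, np.where(cols)[0]] = boosted
    counts_df = pd.DataFrame(counts, index=genes, columns=samples["sample_id"])
    expression = mx.ExpressionMatrix(
        counts_df, "raw_counts", [f"simulated with seed={config.seed}"]
    )
    return expression, gene_lengths, samples, truth


def simulate_genesets(
    truth: TruthSet,
    n_decoy_sets: int = 50,
    size_range: tuple[int, int] = (5, 100),
    seed: int = 0,
    include_markers: bool = True,
) -> GeneSetCatalog:
    """Catalog holding the planted IFN set, one set per module, marker sets
    and random decoy sets drawn from the gene universe."""
    lo, hi = size_range
    if lo < 1 or hi > len(truth.genes) or lo > hi:
        raise ValueError("invalid size range")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {"IFN_TYPE_I_SYNTH": list(truth.ifn_genes)}
    descriptions = {"IFN_TYPE_I_SYNTH": "planted interferon-response genes"}
    modules: dict[int, list[str]] = {}
    for gene, m in truth.module_assignment.items():
        modules.setdefault(m, []).append(gene)
    for m in sorted(modules):
        name = f"MODULE_{m}_SYNTH"
        sets[name] = modules[m]
        descriptions[name] = f"planted co-regulated module {m}"
    if include_markers:
        for ct, marker_list in truth.marker_genes.items():
            name = f"MARKERS_{ct}"
            sets[name] = list(marker_list)
            descriptions[name] = f"planted {ct} marker genes"
    universe = np.array(truth.genes)
    for i in range(1, n_decoy_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        name = f"DECOY_{i:03d}"
        sets[name] = list(rng.choice(universe, size=size, replace=False))
        descriptions[name] = "random decoy set"
    return GeneSetCatalog(sets, descriptions, provenance="simulate_genesets")


def simulate_lr_table(
    truth: TruthSet, n_decoy_pairs: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Ligand-receptor table: planted events plus random decoy pairs."""
    rng = np.random.default_rng(seed)
    rows = [
        (e["ligand"], e["receptor"], e["category"]) for e in truth.lr_events
    ]
    used = {(lig, rec) for lig, rec, _ in rows}
    planted_genes = {g for e in truth.lr_events for g in (e["ligand"], e["receptor"])}
    pool = [g for g in truth.genes if g not in planted_genes]
    while len(rows) < len(truth.lr_events) + n_decoy_pairs:
        lig, rec = rng.choice(pool, size=2, replace=False)
        if (lig, rec) in used:
            continue
        used.add((lig, rec))
        rows.append((lig, rec, str(rng.choice(LR_CATEGORIES))))
    table = pd.DataFrame(rows, columns=["ligand", "receptor", "category"])
    bad = set(table["category"]) - set(LR_CATEGORIES)
    if bad:
        raise ValueError(f"unknown ligand-receptor categories: {bad}")
    return table


def write_dataset(
    outdir: str | Path,
    expression: mx.ExpressionMatrix,
    gene_lengths: Mapping[str, float],
    samples: pd.DataFrame,
    truth: TruthSet,
    catalog: GeneSetCatalog | None = None,
    lr_table: pd.DataFrame | None = None,
) -> None:
    """Write the simulator's external files into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression.to_tsv(outdir / "counts.tsv")
    mx.write_gene_lengths(gene_lengths, outdir / "gene_lengths.tsv")
    mx.write_samples(samples, outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")
    if catalog is not None:
        write_gmt(catalog, outdir / "sets.gmt")
    if lr_table is not None:
        lr_table.to_csv(outdir / "lr_pairs.tsv", sep="\t", index=False)
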