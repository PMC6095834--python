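"""Synthetic pooled dropout screens with known ground truth.

The generator emulates a kinome-scale TRC-style screen: a library of
``n_genes`` genes with ``hairpins_per_gene`` hairpins each is "screened" in a
panel of cell lines, in replicate, at a chosen library coverage.  Baseline
hairpin abundances are skewed (log-normal), sequencing depth per sample is
``coverage x n_hairpins`` reads allocated multinomially, and biological
replicate noise is gamma-Poisson (negative binomial).  Lethal effects are
planted as true T1/T0 fold changes: *common* lethals act in every line,
*genotype* lethals only in mutant lines, and a small fraction of hairpins in
neutral genes carry off-target depletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .screen_io import CountTable, HairpinLibrary

GENOTYPES = ("wildtype", "mutant")


@dataclass(frozen=True)
class SimulationDesign:
    """Shape and sampling parameters of a simulated screen.

    Parameters
    ----------
    n_lines
        Number of cell lines in the panel.
    genotype_labels
        One label per line, each ``"wildtype"`` or ``"mutant"``.
    n_genes, hairpins_per_gene
        Library size (defaults mirror a 535-gene kinome library with five
        hairpins per gene).
    replicates
        Infection replicates per line per timepoint.
    coverage
        Expected mean reads per hairpin per sample; the in-silico analogue
        of library representation.
    dispersion
        Negative-binomial overdispersion of replicate counts
        (variance = mu + dispersion * mu^2).
    seed
        Seed for the generator; identical seeds give identical screens.
    line_names
        Optional explicit line names; derived from genotypes otherwise.
    """

    n_lines: int
    genotype_labels: tuple[str, ...]
    n_genes: int = 535
    hairpins_per_gene: int = 5
    replicates: int = 3
    coverage: float = 1000.0
    dispersion: float = 0.05
    seed: int = 0
    line_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.hairpins_per_gene < 1:
            raise ParameterError("hairpins_per_gene must be >= 1")
        if self.replicates < 2:
            raise ParameterError("replicates must be >= 2")
        if self.coverage <= 0:
            raise ParameterError("coverage must be > 0")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if len(self.genotype_labels) != self.n_lines:
            raise ParameterError("genotype_labels length must equal n_lines")
        if not set(self.genotype_labels) <= set(GENOTYPES):
            raise ParameterError(f"genotypes must be in {GENOTYPES}")
        if self.line_names is not None and len(self.line_names) != self.n_lines:
            raise ParameterError("line_names length must equal n_lines")

    @property
    def lines(self) -> tuple[str, ...]:
        if self.line_names is not None:
            return self.line_names
        names, n_wt, n_mut = [], 0, 0
        for g in self.genotype_labels:
            if g == "wildtype":
                n_wt += 1
                names.append(f"WT{n_wt:02d}")
            else:
                n_mut += 1
                names.append(f"MUT{n_mut:02d}")
        return tuple(names)

    @property
    def genotypes(self) -> pd.Series:
        return pd.Series(list(self.genotype_labels), index=list(self.lines),
                         name="genotype")


def cohort_design(
    n_wildtype: int = 5,
    n_mutant: int = 9,
    *,
    seed: int = 0,
    **kwargs,
) -> SimulationDesign:
    """Convenience constructor for a wildtype/mutant cell-line panel."""
    labels = ("wildtype",) * n_wildtype + ("mutant",) * n_mutant
    return SimulationDesign(
        n_lines=n_wildtype + n_mutant, genotype_labels=labels, seed=seed,
        **kwargs,
    )


@dataclass(frozen=True)
class EffectModel:
    """Planted lethal effects: which genes drop out, and how strongly.

    ``common_lethals`` and ``genotype_lethals`` map gene symbols to
    per-hairpin true fold changes in (0, 1]; genotype lethals act only in
    mutant lines.  ``off_target_rate`` is the fraction of hairpins in
    neutral genes given a random (line-independent) depletion effect,
    modelling single rogue hairpins.
    """

    common_lethals: Mapping[str, Sequence[float]] = field(default_factory=dict)
    genotype_lethals: Mapping[str, Sequence[float]] = field(default_factory=dict)
    off_target_rate: float = 0.02
    off_target_fc_range: tuple[float, float] = (0.2, 0.8)
    baseline_logmean_sd: float = 0.5  # log10 scale

    def __post_init__(self) -> None:
        overlap = set(self.common_lethals) & set(self.genotype_lethals)
        if overlap:
            raise ParameterError(f"genes in both effect sets: {sorted(overlap)}")
        for name, fcs in {**self.common_lethals, **self.genotype_lethals}.items():
            arr = np.asarray(list(fcs), dtype=float)
            if np.any(arr <= 0):
                raise ParameterError(f"gene {name}: fold changes must be > 0")
        if not 0 <= self.off_target_rate <= 1:
            raise ParameterError("off_target_rate must be in [0, 1]")

    @property
    def lethal_genes(self) -> set[str]:
        return set(self.common_lethals) | set(self.genotype_lethals)


@dataclass
class SimTruth:
    """Ground truth of a simulated screen.

    ``gene_status`` is a boolean gene x line frame (True = lethal in that
    line); ``hairpin_fc`` is the hairpin x line frame of true T1/T0 fold
    changes (off-target effects included).
    """

    gene_status: pd.DataFrame
    hairpin_fc: pd.DataFrame

    def lethal_genes(self, line: str) -> set[str]:
        col = self.gene_status[line]
        return set(col.index[col])


def simulate_library(design: SimulationDesign) -> HairpinLibrary:
    """Build a synthetic hairpin library with random 21-nt target sequences.

    Gene symbols are ``G0001 ...``; hairpin ids append ``_sh1 ...``.
    Deterministic under ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"G{i + 1:04d}" for i in range(design.n_genes)]
    records = []
    seen: set[str] = set()
    for gene in genes:
        for h in range(design.hairpins_per_gene):
            while True:
                seq = "".join(rng.choice(list("ACGT"), size=21))
                if seq not in seen:
                    seen.add(seq)
                    break
            records.append((f"{gene}_sh{h + 1}", gene, seq))
    df = pd.DataFrame(records, columns=["hairpin_id", "gene", "sequence"])
    return HairpinLibrary(df.set_index("hairpin_id"))


def random_effects(
    library: HairpinLibrary,
    *,
    n_common: int = 5,
    n_genotype: int = 5,
    fc_range: tuple[float, float] = (0.1, 0.3),
    off_target_rate: float = 0.02,
    seed: int = 0,
) -> EffectModel:
    """Draw a default effect model: planted lethals with uniform per-hairpin
    fold changes in ``fc_range`` over randomly chosen disjoint gene sets."""
    rng = np.random.default_rng(seed)
    genes = list(library.genes)
    if n_common + n_genotype > len(genes):
        raise ParameterError("more planted lethals than genes")
    chosen = rng.choice(genes, size=n_common + n_genotype, replace=False)
    hp_per_gene = library.gene_of().value_counts()

    def draw(gene: str) -> list[float]:
        return rng.uniform(*fc_range, size=int(hp_per_gene[gene])).tolist()

    return EffectModel(
        common_lethals={g: draw(g) for g in chosen[:n_common]},
        genotype_lethals={g: draw(g) for g in chosen[n_common:]},
        off_target_rate=off_target_rate,
    )


def _true_fold_changes(
    library: HairpinLibrary, effects: EffectModel, rng: np.random.Generator
) -> pd.Series:
    """Line-independent per-hairpin FC (genotype effects applied later)."""
    fc = pd.Series(1.0, index=library.hairpin_ids)
    gene_of = library.gene_of()
    # off-target depletion in neutral genes only
    neutral = gene_of.index[~gene_of.isin(list(effects.lethal_genes))]
    n_off = int(round(effects.off_target_rate * len(neutral)))
    if n_off:
        hit = rng.choice(neutral, size=n_off, replace=False)
        lo, hi = effects.off_target_fc_range
        fc[hit] = rng.uniform(lo, hi, size=n_off)
    return fc


def simulate_screen(
    library: HairpinLibrary,
    design: SimulationDesign,
    effects: EffectModel | None = None,
) -> tuple[CountTable, SimTruth]:
    """Simulate T0/T1 counts for every line in the design.

    For each sample, expected hairpin proportions are the (skewed) baseline
    abundances, multiplied at T1 by the true fold changes for that line.
    A per-sample depth of ``coverage x n_hairpins`` reads is allocated
    multinomially; replicate overdispersion enters as gamma noise on the
    proportions (the gamma-Poisson construction of the negative binomial).

    Returns the count table and the ground truth used to generate it.
    """
    if effects is None:
        effects = EffectModel()
    missing = effects.lethal_genes - set(library.genes)
    if missing:
        raise ParameterError(f"effect genes absent from library: {sorted(missing)}")
    n_hp = len(library)
    expected = design.n_genes * design.hairpins_per_gene
    if n_hp != expected:
        raise ParameterError(
            f"library has {n_hp} hairpins, design implies {expected}"
        )

    rng = np.random.default_rng(design.seed)
    gene_of = library.gene_of()
    baseline = 10.0 ** rng.normal(0.0, effects.baseline_logmean_sd, size=n_hp)
    base_fc = _true_fold_changes(library, effects, rng)

    # per-line fold-change vectors and truth tables
    fc_by_line: dict[str, np.ndarray] = {}
    status = pd.DataFrame(False, index=library.genes, columns=list(design.lines))
    for line, genotype in zip(design.lines, design.genotype_labels):
        fc = base_fc.copy()
        for gene, fcs in effects.common_lethals.items():
            fc[gene_of == gene] = np.asarray(fcs, dtype=float)
            status.loc[gene, line] = True
        if genotype == "mutant":
            for gene, fcs in effects.genotype_lethals.items():
                fc[gene_of == gene] = np.asarray(fcs, dtype=float)
                status.loc[gene, line] = True
        fc_by_line[line] = fc.to_numpy()

    depth = int(round(design.coverage * n_hp))
    shape = 1.0 / design.dispersion if design.dispersion > 0 else None

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for line in design.lines:
        for tp in ("T0", "T1"):
            mean = baseline if tp == "T0" else baseline * fc_by_line[line]
            for rep in range(1, design.replicates + 1):
                if shape is None:
                    w = mean
                else:
                    w = mean * rng.gamma(shape, 1.0 / shape, size=n_hp)
                sample_id = f"{line}_{tp}_r{rep}"
                columns[sample_id] = rng.multinomial(depth, w / w.sum())
                meta_rows.append((sample_id, line, tp, rep))

    counts = pd.DataFrame(columns, index=library.hairpin_ids)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "cell_line", "timepoint", "replicate"]
    ).set_index("sample_id")
    hairpin_fc = pd.DataFrame(
        {line: fc_by_line[line] for line in design.lines},
        index=library.hairpin_ids,
    )
    return CountTable(counts, samples), SimTruth(status, hairpin_fc)


def write_truth(truth: SimTruth, status_path, fc_path) -> None:
    truth.gene_status.astype(int).to_csv(status_path, sep="\t", index_label="gene")
    truth.hairpin_fc.to_csv(fc_path, sep="\t", index_label="hairpin_id")
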