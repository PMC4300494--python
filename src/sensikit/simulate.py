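"""Synthetic screens, amplicon reads, proteome tables and viability curves with
planted, recoverable ground truth.

All generators are driven by a single seed and are bit-reproducible: the same
config yields byte-identical tables and reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .quant import (
    CONSTANT_TAIL,
    HAIRPIN_LEN,
    INDEX_LEN,
    CountMatrix,
    HairpinLibrary,
    SampleSheet,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSensitizer:
    """A gene whose hairpins deplete in the treated arm(s).

    ``fc_day7``/``fc_day4`` multiply the treated-sample mean relative to DMSO
    at the matching day. ``arms=None`` means the effect is shared by every arm
    in the config; ``n_hairpins=None`` affects all of the gene's hairpins.
    """

    gene: str
    fc_day7: float
    fc_day4: float = 1.0
    arms: tuple[str, ...] | None = None
    n_hairpins: int | None = None


@dataclass(frozen=True)
class PlantedEssential:
    """A gene depleted in all post-infection samples relative to reference."""

    gene: str
    fc_dmso: float


@dataclass
class ScreenSimConfig:
    n_genes: int = 50
    hairpins_per_gene: int = 4
    n_pools: int = 4
    depth_mean: float = 500.0
    dispersion: float = 0.05  # NB alpha: var = mu + alpha mu^2
    n_replicates: int = 3
    planted_sensitizers: tuple[PlantedSensitizer, ...] = ()
    planted_essentials: tuple[PlantedEssential, ...] = ()
    arms: tuple[str, ...] = ("PLX", "SCH")
    days: tuple[int, ...] = (4, 7)
    abundance_sigma: float = 0.5  # log-normal per-hairpin representation skew
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.hairpins_per_gene < 1:
            raise ConfigError("hairpins_per_gene must be >= 1")
        for s in self.planted_sensitizers:
            if s.fc_day7 <= 0 or s.fc_day4 <= 0:
                raise ConfigError(f"planted fold changes must be > 0 ({s.gene})")
        for e in self.planted_essentials:
            if e.fc_dmso <= 0:
                raise ConfigError(f"planted fold changes must be > 0 ({e.gene})")
        if not all(a in ("PLX", "SCH") for a in self.arms):
            raise ConfigError("arms must be a subset of {PLX, SCH}")


def _random_distinct_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    bases = np.array(list("ACGT"))
    while len(out) < n:
        seq = "".join(bases[rng.integers(0, 4, size=k)])
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _build_sample_sheet(cfg: ScreenSimConfig, rng: np.random.Generator) -> SampleSheet:
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        rows.append(("ref_r%d" % rep, "reference", "none", 0, rep))
        for day in cfg.days:
            rows.append((f"dmso_d{day}_r{rep}", "DMSO", "none", day, rep))
            for arm in cfg.arms:
                rows.append((f"{arm.lower()}_d{day}_r{rep}", "treated", arm, day, rep))
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "treatment", "day", "replicate"])
    df["index"] = _random_distinct_kmers(rng, len(df), INDEX_LEN)
    return SampleSheet(df[["sample_id", "index", "condition", "treatment", "day", "replicate"]])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[HairpinLibrary, SampleSheet, CountMatrix, pd.DataFrame]:
    """Simulate a pooled dropout screen with planted sensitizer/essential genes.

    Counts are NB(mu, alpha) with mu = depth * hairpin abundance * condition
    fold change * sample size factor. The returned truth table has one row per
    gene per contrast (treated arms at each day vs DMSO, plus DMSO vs
    reference) with the true fold change, and one row per hairpin of each
    planted gene recording whether that hairpin carries the effect.
    """
    rng = np.random.default_rng(cfg.seed)
    n_hp = cfg.n_genes * cfg.hairpins_per_gene

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    planted_names = [s.gene for s in cfg.planted_sensitizers] + [
        e.gene for e in cfg.planted_essentials
    ]
    if len(set(planted_names)) != len(planted_names):
        raise ConfigError("each planted gene may appear only once")
    if len(planted_names) > cfg.n_genes:
        raise ConfigError("more planted genes than genes")
    for i, name in enumerate(planted_names):
        genes[i] = name

    lib = HairpinLibrary(
        pd.DataFrame(
            {
                "hairpin_id": [str(i + 1) for i in range(n_hp)],
                "gene": np.repeat(genes, cfg.hairpins_per_gene),
                "target_sequence": _random_distinct_kmers(rng, n_hp, HAIRPIN_LEN),
                "pool": [f"pool{(i % cfg.n_pools) + 1}" for i in range(n_hp)],
            }
        )
    )
    sheet = _build_sample_sheet(cfg, rng)

    abundance = rng.lognormal(
        mean=-cfg.abundance_sigma**2 / 2, sigma=cfg.abundance_sigma, size=n_hp
    )
    lo, hi = cfg.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sheet)))

    hp_gene = lib.df["gene"].to_numpy()
    # per-hairpin multipliers for the sensitizer effect (1 where unaffected)
    sens_mult: dict[tuple[str, str, int], np.ndarray] = {}
    hairpin_effect_rows = []
    for s in cfg.planted_sensitizers:
        idx = np.flatnonzero(hp_gene == s.gene)
        if idx.size == 0:
            raise ConfigError(f"planted sensitizer gene {s.gene!r} has no hairpins")
        affected = idx
        if s.n_hairpins is not None:
            affected = rng.choice(idx, size=min(s.n_hairpins, idx.size), replace=False)
        arms = s.arms if s.arms is not None else cfg.arms
        for arm in arms:
            for day, fc in ((4, s.fc_day4), (7, s.fc_day7)):
                if day not in cfg.days:
                    continue
                mult = np.ones(n_hp)
                mult[affected] = fc
                sens_mult[(s.gene, arm, day)] = mult
        for i in idx:
            hairpin_effect_rows.append(
                {
                    "entity_id": lib.df.loc[i, "hairpin_id"],
                    "entity_type": "hairpin",
                    "contrast": "sensitizer",
                    "true_fc": s.fc_day7 if i in affected else 1.0,
                    "is_planted": bool(i in affected),
                }
            )

    ess_mult = np.ones(n_hp)
    for e in cfg.planted_essentials:
        idx = np.flatnonzero(hp_gene == e.gene)
        if idx.size == 0:
            raise ConfigError(f"planted essential gene {e.gene!r} has no hairpins")
        ess_mult[idx] = e.fc_dmso

    cols = {}
    for j, row in sheet.df.iterrows():
        mult = np.ones(n_hp)
        if row["condition"] != "reference":
            mult = mult * ess_mult
        if row["condition"] == "treated":
            for (gene, arm, day), m in sens_mult.items():
                if arm == row["treatment"] and day == row["day"]:
                    mult = mult * m
        mu = cfg.depth_mean * abundance * mult * size_factors[j]
        cols[row["sample_id"]] = _nb_draw(rng, mu, cfg.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(lib.hairpin_ids, name="hairpin_id"))
    cm = CountMatrix(counts, sheet)

    truth_rows = []
    sens_by_gene = {s.gene: s for s in cfg.planted_sensitizers}
    ess_by_gene = {e.gene: e for e in cfg.planted_essentials}
    for g in genes:
        for arm in cfg.arms:
            for day in cfg.days:
                s = sens_by_gene.get(g)
                fc = 1.0
                if s is not None and arm in (s.arms if s.arms is not None else cfg.arms):
                    fc = s.fc_day7 if day == 7 else s.fc_day4
                truth_rows.append(
                    {
                        "entity_id": g,
                        "entity_type": "gene",
                        "contrast": f"{arm}_vs_DMSO_day{day}",
                        "true_fc": fc,
                        "is_planted": fc != 1.0,
                    }
                )
        e = ess_by_gene.get(g)
        truth_rows.append(
            {
                "entity_id": g,
                "entity_type": "gene",
                "contrast": "DMSO_vs_reference",
                "true_fc": e.fc_dmso if e is not None else 1.0,
                "is_planted": e is not None,
            }
        )
    truth = pd.DataFrame(truth_rows + hairpin_effect_rows)
    return lib, sheet, cm, truth


# ---------------------------------------------------------------------------
# Amplicon reads
# ---------------------------------------------------------------------------

_MUT = {
    "A": np.array(list("CGT")),
    "C": np.array(list("AGT")),
    "G": np.array(list("ACT")),
    "T": np.array(list("ACG")),
}


def simulate_amplicon_reads(
    cm: CountMatrix,
    lib: HairpinLibrary,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Iterator[SeqRecord]:
    """Yield one FASTQ record per count unit.

    Read = 6-bp sample index + 21-nt hairpin sense sequence + constant tail,
    with independent per-base substitution errors at ``error_rate``.
    """
    if not 0 <= error_rate < 1:
        raise ConfigError("error_rate must be in [0, 1)")
    cm.validate_against(lib)
    index_of = cm.samples.index_of
    seq_of = lib.sequence_of
    rng = np.random.default_rng(seed)
    for sample in cm.samples.sample_ids:
        idx = index_of[sample]
        col = cm.counts[sample]
        for hid, n in col.items():
            if n == 0:
                continue
            template = idx + seq_of[hid] + CONSTANT_TAIL
            length = len(template)
            for i in range(int(n)):
                seq = template
                if error_rate > 0:
                    n_err = rng.binomial(length, error_rate)
                    if n_err:
                        pos = rng.choice(length, size=n_err, replace=False)
                        chars = list(seq)
                        for p in pos:
                            chars[p] = _MUT[chars[p]][rng.integers(0, 3)]
                        seq = "".join(chars)
                rec = SeqRecord(
                    Seq(seq),
                    id=f"{sample}:{hid}:{i}",
                    description="",
                )
                rec.letter_annotations["phred_quality"] = [40] * length
                yield rec


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    """Write records to (optionally gzipped) FASTQ; returns the record count."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        return SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------


@dataclass
class LocProbModel:
    """Two-component Beta mixture for phosphosite localization probabilities."""

    frac_confident: float = 0.8
    confident_beta: tuple[float, float] = (12.0, 1.0)
    ambiguous_beta: tuple[float, float] = (2.0, 2.0)

    def mass_above(self, threshold: float) -> float:
        from scipy.stats import beta

        return self.frac_confident * beta.sf(threshold, *self.confident_beta) + (
            1 - self.frac_confident
        ) * beta.sf(threshold, *self.ambiguous_beta)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        conf = rng.random(size) < self.frac_confident
        out = np.where(
            conf,
            rng.beta(*self.confident_beta, size=size),
            rng.beta(*self.ambiguous_beta, size=size),
        )
        return out


@dataclass
class ProteomeSimConfig:
    n_proteins: int = 1000
    n_replicates: int = 3
    frac_regulated: float = 0.05
    effect_log2fc_range: tuple[float, float] = (0.8, 2.0)  # planted |log2 FC|
    noise_sd: float = 0.2
    frac_phospho: float = 0.3
    loc_prob_model: LocProbModel = field(default_factory=LocProbModel)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.frac_regulated <= 1:
            raise ConfigError("frac_regulated must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0 <= self.frac_phospho <= 1:
            raise ConfigError("frac_phospho must lie in [0, 1]")


def simulate_proteome(
    cfg: ProteomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate triplex ratio tables (protein + phosphosite) with planted effects.

    Per protein and replicate: M/L log2 ratio ~ Normal(true 1d effect, sd),
    H/L ~ Normal(true 3d effect, sd) and H/M ~ Normal(3d - 1d effect, sd) with
    independent noise. Regulated proteins get effects of the configured
    magnitude (random sign, shared across both timepoint contrasts).
    """
    rng = np.random.default_rng(cfg.seed)
    n, reps = cfg.n_proteins, cfg.n_replicates
    ids = [f"P{i:05d}" for i in range(n)]
    genes = [f"PG{i:05d}" for i in range(n)]

    regulated = rng.random(n) < cfg.frac_regulated
    lo, hi = cfg.effect_log2fc_range
    magnitude = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    mu_1d = np.where(regulated, sign * magnitude, 0.0)
    # 3d effect shares direction, independently drawn magnitude
    mu_3d = np.where(regulated, sign * rng.uniform(lo, hi, size=n), 0.0)

    table = {"protein_id": ids, "gene": genes}
    for r in range(1, reps + 1):
        table[f"ml_log2_{r}"] = mu_1d + rng.normal(0, cfg.noise_sd, size=n)
    for r in range(1, reps + 1):
        table[f"hl_log2_{r}"] = mu_3d + rng.normal(0, cfg.noise_sd, size=n)
    for r in range(1, reps + 1):
        table[f"hm_log2_{r}"] = (mu_3d - mu_1d) + rng.normal(0, cfg.noise_sd, size=n)
    proteins = pd.DataFrame(table)

    is_phospho = rng.random(n) < cfg.frac_phospho
    p_idx = np.flatnonzero(is_phospho)
    sites = {
        "protein_id": [ids[i] for i in p_idx],
        "position": rng.integers(1, 800, size=p_idx.size),
        "residue": rng.choice(list("STY"), p=[0.75, 0.2, 0.05], size=p_idx.size),
        "localization_prob": cfg.loc_prob_model.draw(rng, p_idx.size),
    }
    for r in range(1, reps + 1):
        sites[f"ml_log2_{r}"] = mu_1d[p_idx] + rng.normal(0, cfg.noise_sd, size=p_idx.size)
    for r in range(1, reps + 1):
        sites[f"hl_log2_{r}"] = mu_3d[p_idx] + rng.normal(0, cfg.noise_sd, size=p_idx.size)
    for r in range(1, reps + 1):
        sites[f"hm_log2_{r}"] = (mu_3d - mu_1d)[p_idx] + rng.normal(
            0, cfg.noise_sd, size=p_idx.size
        )
    phospho = pd.DataFrame(sites)

    truth = pd.concat(
        [
            pd.DataFrame(
                {
                    "entity_id": ids,
                    "entity_type": "protein",
                    "contrast": "1d_vs_ctrl",
                    "true_log2fc": mu_1d,
                    "is_planted": regulated,
                }
            ),
            pd.DataFrame(
                {
                    "entity_id": ids,
                    "entity_type": "protein",
                    "contrast": "3d_vs_ctrl",
                    "true_log2fc": mu_3d,
                    "is_planted": regulated,
                }
            ),
        ],
        ignore_index=True,
    )
    return proteins, phospho, truth


# ---------------------------------------------------------------------------
# Viability curves
# ---------------------------------------------------------------------------


def simulate_viability(
    concentrations: Sequence[float],
    top: float = 100.0,
    bottom: float = 0.0,
    ic50: float = 0.5,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent-viability readings from a 4PL curve with Gaussian noise."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    v = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
    rows = []
    for r in range(1, n_replicates + 1):
        noisy = v + rng.normal(0, noise_sd, size=conc.size) if noise_sd > 0 else v
        for c, val in zip(conc, noisy):
            rows.append({"concentration": c, "replicate": r, "percent_viability": val})
    return pd.DataFrame(rows)
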