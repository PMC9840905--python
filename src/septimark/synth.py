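"""Synthetic burn-sepsis cohorts with planted, recoverable ground truth.

The generator emulates the statistical structure the downstream stages
assume: healthy controls (C) plus two burn groups (NS = no subsequent
sepsis, S = sepsis) followed over post-burn days; per-gene carrier
frequencies of qualifying variants that may differ between S and NS;
log-normal plasma intensities (one shared baseline per feature from
Normal(20, 2) on the log2 scale, a DIA-like range) with additive planted
effects and Gaussian log2 noise; intensity-dependent (left-censoring-like)
missingness on the protein tables; and day-1 marker separations with an
analytically known binormal AUC, Phi(d / sqrt(2)).

All randomness flows from one integer seed through a
``numpy.random.SeedSequence``; each table draws from its own spawned
sub-stream, so adding or resizing one table never perturbs the others.
Planted effects are echoed verbatim into a :class:`PlantedTruth` record so
recovery tests can score sensitivity and false discovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigError
from .matrix import AbundanceMatrix, validate_samples
from .trends import signs_for_profile

CONTRASTS = ("NSvsC", "SvsC", "SvsNS")

_CARRIER_CATEGORIES = (3, 4, 5)
_CARRIER_CATEGORY_P = (0.7, 0.2, 0.1)  # mostly uncertain-significance, some (likely) pathogenic
_BENIGN_RATE = 0.05                    # per (gene, sample) chance of a category-1/2 record
_INDEL_RATE = 0.15


def gene_name(i: int) -> str:
    return f"GENE{i + 1:04d}"


def mirna_name(i: int) -> str:
    return f"syn-miR-{i + 1:04d}"


def protein_name(i: int) -> str:
    return f"PROT{i + 1:04d}"


@dataclass(frozen=True)
class CohortConfig:
    """Everything that defines a synthetic cohort, plants included.

    Planted entries reference features by their generated names
    (``GENE0001``, ``syn-miR-0001``, ``PROT0001``, ...); an unknown name is
    a configuration error naming the offending field.
    """

    n_control: int = 10
    n_ns: int = 24
    n_s: int = 16
    days: tuple[int, ...] = (0, 1, 3, 5, 7)
    n_genes: int = 200
    n_mirna: int = 150
    n_protein: int = 400
    #: (gene, carrier_freq_S, carrier_freq_NS) of qualifying (category >= 3) variants
    planted_susceptibility: tuple[tuple[str, float, float], ...] = ()
    #: (feature, log2 fold, contrast in {NSvsC, SvsC, SvsNS})
    planted_mirna: tuple[tuple[str, float, str], ...] = ()
    #: (feature, profile_ns or None, profile_s or None, step magnitude in log2 units)
    planted_trend: tuple[tuple[str, int | None, int | None, float], ...] = ()
    #: (feature, standardized day-1 mean separation d; AUC = Phi(d / sqrt 2))
    planted_marker: tuple[tuple[str, float], ...] = ()
    noise_sigma: float = 0.5
    missing_rate_base: float = 0.1
    missing_intensity_slope: float = 1.0
    background_carrier_freq: float = 0.05
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_control", "n_ns", "n_s", "n_genes", "n_mirna", "n_protein"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count, got {getattr(self, name)}")
        if not self.days or list(self.days) != sorted(set(self.days)):
            raise ConfigError(f"days must be distinct and ascending, got {self.days}")
        if not set(self.days) <= {0, 1, 3, 5, 7}:
            raise ConfigError(f"days must be a subset of (0, 1, 3, 5, 7), got {self.days}")
        if 0 not in self.days:
            raise ConfigError("days must include 0 (the healthy-control time point)")
        if not self.noise_sigma > 0:
            raise ConfigError(f"noise_sigma must be > 0, got {self.noise_sigma}")
        for name in ("missing_rate_base", "background_carrier_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        genes = {gene_name(i) for i in range(self.n_genes)}
        seen: set[str] = set()
        for gene, fs, fns in self.planted_susceptibility:
            if gene not in genes:
                raise ConfigError(
                    f"planted_susceptibility references unknown gene {gene!r} "
                    f"(n_genes = {self.n_genes})")
            if gene in seen:
                raise ConfigError(f"planted_susceptibility lists {gene!r} twice")
            seen.add(gene)
            for v in (fs, fns):
                if not 0 <= v <= 1:
                    raise ConfigError(f"planted_susceptibility frequency {v} outside [0, 1]")
        mirnas = {mirna_name(i) for i in range(self.n_mirna)}
        seen = set()
        for feat, _, contrast in self.planted_mirna:
            if feat not in mirnas:
                raise ConfigError(
                    f"planted_mirna references unknown feature {feat!r} (n_mirna = {self.n_mirna})")
            if feat in seen:
                raise ConfigError(f"planted_mirna lists {feat!r} twice")
            seen.add(feat)
            if contrast not in CONTRASTS:
                raise ConfigError(f"planted_mirna contrast {contrast!r} not in {CONTRASTS}")
        proteins = {protein_name(i) for i in range(self.n_protein)}
        seen = set()
        for feat, p_ns, p_s, mag in self.planted_trend:
            if feat not in proteins:
                raise ConfigError(
                    f"planted_trend references unknown feature {feat!r} "
                    f"(n_protein = {self.n_protein})")
            if feat in seen:
                raise ConfigError(f"planted_trend lists {feat!r} twice (or clashes with a marker)")
            seen.add(feat)
            for pid in (p_ns, p_s):
                if pid is not None and pid not in range(8):
                    raise ConfigError(f"planted_trend profile id {pid!r} must be 0..7 or None")
            if not mag > 0:
                raise ConfigError(f"planted_trend step magnitude must be > 0, got {mag}")
        for feat, d in self.planted_marker:
            if feat not in proteins:
                raise ConfigError(
                    f"planted_marker references unknown feature {feat!r} "
                    f"(n_protein = {self.n_protein})")
            if feat in seen:
                raise ConfigError(
                    f"planted_marker feature {feat!r} is already planted in the protein table")
            seen.add(feat)
            if not np.isfinite(d):
                raise ConfigError(f"planted_marker separation must be finite, got {d}")


@dataclass
class PlantedTruth:
    """Verbatim echo of the plants, keyed by table."""

    susceptibility: dict[str, tuple[float, float]] = field(default_factory=dict)
    mirna: dict[str, tuple[float, str]] = field(default_factory=dict)
    trend: dict[str, tuple[int | None, int | None, float]] = field(default_factory=dict)
    marker: dict[str, float] = field(default_factory=dict)

    def trend_differential_features(self) -> frozenset[str]:
        """Planted trend features whose NS/S profile pair is differential by design.

        Differential means: classes opposite, or exactly one path flat.  The
        rule is evaluated on the planted profile ids through the same class
        logic the analysis uses, so it is invariant to the class-map choice.
        """
        from .trends import classify_trend, trend_differential
        out = set()
        for feat, (p_ns, p_s, _) in self.trend.items():
            call = trend_differential(classify_trend(p_ns), classify_trend(p_s))
            if call.is_differential:
                out.add(feat)
        return frozenset(out)

    def to_json(self, path=None) -> str:
        doc = {
            "susceptibility": {g: list(v) for g, v in sorted(self.susceptibility.items())},
            "mirna": {f: list(v) for f, v in sorted(self.mirna.items())},
            "trend": {f: list(v) for f, v in sorted(self.trend.items())},
            "marker": dict(sorted(self.marker.items())),
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "PlantedTruth":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls(
            susceptibility={g: tuple(v) for g, v in doc["susceptibility"].items()},
            mirna={f: (float(v[0]), str(v[1])) for f, v in doc["mirna"].items()},
            trend={f: (v[0] if v[0] is None else int(v[0]),
                       v[1] if v[1] is None else int(v[1]), float(v[2]))
                   for f, v in doc["trend"].items()},
            marker={f: float(d) for f, d in doc["marker"].items()},
        )


@dataclass
class SimulatedCohort:
    """All tables of one synthetic cohort, plus the planted truth."""

    variants: pd.DataFrame
    mirna: AbundanceMatrix
    protein: dict[int, AbundanceMatrix]  # day -> matrix (day 0 = controls)
    samples: pd.DataFrame
    truth: PlantedTruth
    config: CohortConfig

    def write(self, outdir) -> list[str]:
        """Write variants.tsv, samples.tsv, mirna_matrix.tsv, protein_matrix_day{D}.tsv, truth.json."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        written.append("variants.tsv")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        written.append("samples.tsv")
        self.mirna.to_tsv(outdir / "mirna_matrix.tsv")
        written.append("mirna_matrix.tsv")
        for day, m in sorted(self.protein.items()):
            name = f"protein_matrix_day{day}.tsv"
            m.to_tsv(outdir / name)
            written.append(name)
        self.truth.to_json(outdir / "truth.json")
        written.append("truth.json")
        return written


def theoretical_auc(d: float) -> float:
    """Binormal AUC of a standardized mean separation d: Phi(d / sqrt 2).

    Symmetric — ``theoretical_auc(-d) == 1 - theoretical_auc(d)`` — with the
    monotone limits 0.5 at d = 0 and 1.0 as d grows.
    """
    return float(norm.cdf(d / np.sqrt(2.0)))


def _subject_ids(config: CohortConfig) -> tuple[list[str], list[str], list[str]]:
    controls = [f"C{i + 1:03d}" for i in range(config.n_control)]
    ns = [f"NS{i + 1:03d}" for i in range(config.n_ns)]
    s = [f"S{i + 1:03d}" for i in range(config.n_s)]
    return controls, ns, s


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw one cohort.  Identical configs (seed included) give identical tables."""
    config.validate()
    controls, ns_subjects, s_subjects = _subject_ids(config)
    patients = ns_subjects + s_subjects

    # Sub-streams in fixed order; resizing one table leaves the others alone.
    root = np.random.SeedSequence(config.seed)
    ss_var, ss_mirna, ss_protein, ss_missing = root.spawn(4)
    rng_var = np.random.default_rng(ss_var)
    rng_mirna = np.random.default_rng(ss_mirna)
    rng_protein = np.random.default_rng(ss_protein)
    rng_missing = np.random.default_rng(ss_missing)

    # -- sample metadata ----------------------------------------------------
    rows = [{"sample_id": c, "group": "C", "day": 0} for c in controls]
    # subject-level entries (genomics / miRNA draw at enrollment)
    rows += [{"sample_id": p, "group": "NS" if p in set(ns_subjects) else "S", "day": 0}
             for p in patients]
    for day in config.days:
        if day == 0:
            continue
        for p in patients:
            rows.append({"sample_id": f"{p}_D{day}",
                         "group": "NS" if p in set(ns_subjects) else "S", "day": day})
    samples = validate_samples(pd.DataFrame(rows, columns=["sample_id", "group", "day"]))

    # -- variants ------------------------------------------------------------
    planted_s = {g: (fs, fns) for g, fs, fns in config.planted_susceptibility}
    var_rows = []
    bg = config.background_carrier_freq
    for gi in range(config.n_genes):
        gene = gene_name(gi)
        fs, fns = planted_s.get(gene, (bg, bg))
        for subj in patients:
            p_carrier = fs if subj in set(s_subjects) else fns
            j = 0
            if rng_var.random() < p_carrier:
                cat = int(rng_var.choice(_CARRIER_CATEGORIES, p=_CARRIER_CATEGORY_P))
                vtype = "INDEL" if rng_var.random() < _INDEL_RATE else "SNV"
                var_rows.append({"sample_id": subj, "gene": gene,
                                 "variant_id": f"{gene}_{subj}_v{j}",
                                 "category": cat, "variant_type": vtype})
                j += 1
            if rng_var.random() < _BENIGN_RATE:
                cat = int(rng_var.integers(1, 3))  # benign / likely benign
                vtype = "INDEL" if rng_var.random() < _INDEL_RATE else "SNV"
                var_rows.append({"sample_id": subj, "gene": gene,
                                 "variant_id": f"{gene}_{subj}_v{j}",
                                 "category": cat, "variant_type": vtype})
    variants = pd.DataFrame(
        var_rows, columns=["sample_id", "gene", "variant_id", "category", "variant_type"])

    # -- miRNA matrix (complete; subjects + controls) -----------------------
    mirna_features = [mirna_name(i) for i in range(config.n_mirna)]
    mirna_samples = controls + patients
    base = rng_mirna.normal(config.baseline_mean, config.baseline_sd, size=config.n_mirna)
    log2m = base[:, None] + rng_mirna.normal(
        0.0, config.noise_sigma, size=(config.n_mirna, len(mirna_samples)))
    col_of = {s: j for j, s in enumerate(mirna_samples)}
    feat_of_m = {f: i for i, f in enumerate(mirna_features)}
    for feat, lfc, contrast in config.planted_mirna:
        i = feat_of_m[feat]
        bump = s_subjects if contrast in ("SvsC", "SvsNS") else ns_subjects
        for subj in bump:
            log2m[i, col_of[subj]] += lfc
    mirna = AbundanceMatrix(
        pd.DataFrame(np.exp2(log2m), index=mirna_features, columns=mirna_samples),
        state="raw")

    # -- protein matrices per day -------------------------------------------
    prot_features = [protein_name(i) for i in range(config.n_protein)]
    feat_of_p = {f: i for i, f in enumerate(prot_features)}
    prot_base = rng_protein.normal(config.baseline_mean, config.baseline_sd,
                                   size=config.n_protein)
    protein: dict[int, AbundanceMatrix] = {}
    for day in config.days:
        offs = {"NS": np.zeros(config.n_protein), "S": np.zeros(config.n_protein)}
        if day == 0:
            cols = controls
        else:
            cols = [f"{p}_D{day}" for p in patients]
            # planted trend steps at day 1 and day 3, held flat afterwards
            for feat, p_ns, p_s, mag in config.planted_trend:
                i = feat_of_p[feat]
                for g, pid in (("NS", p_ns), ("S", p_s)):
                    if pid is None:
                        continue
                    s1, s2 = signs_for_profile(pid)
                    if day == 1:
                        offs[g][i] = s1 * mag
                    elif day >= 3:
                        offs[g][i] = (s1 + s2) * mag
        log2p = prot_base[:, None] + rng_protein.normal(
            0.0, config.noise_sigma, size=(config.n_protein, len(cols)))
        if day != 0:
            for j, subj in enumerate(patients):
                g = "NS" if subj in set(ns_subjects) else "S"
                log2p[:, j] += offs[g]
            if day == 1:
                for feat, dsep in config.planted_marker:
                    i = feat_of_p[feat]
                    for j, subj in enumerate(patients):
                        if subj in set(s_subjects):
                            log2p[i, j] += dsep * config.noise_sigma
        values = pd.DataFrame(np.exp2(log2p), index=prot_features, columns=cols)
        # intensity-dependent missingness: logistic in -(log2 x - median),
        # scaled so the rate at the median intensity equals the base rate
        if config.missing_rate_base > 0:
            z = np.log2(values.to_numpy())
            med = np.median(z)
            p_miss = np.clip(
                2.0 * config.missing_rate_base
                * expit(-config.missing_intensity_slope * (z - med)), 0.0, 1.0)
            mask = rng_missing.random(size=z.shape) < p_miss
            values = values.mask(pd.DataFrame(mask, index=values.index, columns=values.columns))
        protein[day] = AbundanceMatrix(values, state="raw")

    truth = PlantedTruth(
        susceptibility={g: (fs, fns) for g, fs, fns in config.planted_susceptibility},
        mirna={f: (lfc, c) for f, lfc, c in config.planted_mirna},
        trend={f: (p_ns, p_s, mag) for f, p_ns, p_s, mag in config.planted_trend},
        marker=dict(config.planted_marker),
    )
    return SimulatedCohort(variants=variants, mirna=mirna, protein=protein,
                           samples=samples, truth=truth, config=config)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The demo cohort: study-sized groups with a small set of plants.

    Group sizes follow the sequencing cohorts (10 controls, 24 NS, 16 S over
    days 0/1/3/5/7); plants cover every stage — 5 susceptibility genes at
    well-separated carrier frequencies, 4 miRNAs (2 sepsis-specific), 6
    trend-differential proteins, and 2 day-1 markers.
    """
    return CohortConfig(
        planted_susceptibility=(
            (gene_name(0), 0.60, 0.20),
            (gene_name(1), 0.55, 0.15),
            (gene_name(2), 0.50, 0.10),
            (gene_name(3), 0.45, 0.05),
            (gene_name(4), 0.10, 0.45),
        ),
        planted_mirna=(
            (mirna_name(0), 2.0, "NSvsC"),
            (mirna_name(1), 2.0, "SvsC"),
            (mirna_name(2), 1.8, "SvsNS"),
            (mirna_name(3), -1.8, "SvsNS"),
        ),
        planted_trend=(
            (protein_name(0), 7, 0, 1.0),     # opposite: up vs down
            (protein_name(1), 0, 7, 1.0),
            (protein_name(2), None, 7, 1.0),  # trend in S only
            (protein_name(3), None, 0, 1.0),
            (protein_name(4), 7, None, 1.0),  # trend in NS only
            (protein_name(5), 3, None, 1.0),
        ),
        planted_marker=(
            (protein_name(6), 1.5),
            (protein_name(7), 1.2),
        ),
        seed=seed,
    )
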