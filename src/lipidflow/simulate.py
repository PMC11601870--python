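"""Synthetic multi-tissue lipidomics study generator with known ground truth.

Emulates a two-sex, five-group (sedentary plus 1/2/4/8 weeks of endurance
training), nine-compartment rat study with n animals per cell: per-tissue,
per-ESI-mode untargeted feature tables (peak areas with injection-order
drift, periodic pooled-QC and blank injections, intensity-dependent missing
values, spiked internal standards), a targeted oxylipin/N-acylethanolamine
concentration table with its own QC replicates, and a phenotype table whose
temporal templates are linked to designated lipid blocks so that
module-phenotype correlations have known sign.

The abundance model is lognormal: the log2 mean of lipid f in tissue T for
sex s and group g is a class-by-tissue baseline plus lipid-specific offset
plus planted effects (in units of the residual noise SD); sample areas add
animal-block latent factors (the co-expression ground truth), Gaussian
residual noise, and a per-feature multiplicative linear drift along the
injection order. Every planted structure is recorded in a
:class:`GroundTruth` object regenerable exactly from (design, effects, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import parse_lipid_name
from .preprocess import FeatureTable

__all__ = [
    "StudyDesign",
    "EffectSpec",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_study",
    "default_effect_specs",
    "build_lipid_universe",
    "truth_report",
    "DEFAULT_TISSUES",
    "SEXES",
    "GROUPS",
]

DEFAULT_TISSUES = ("BAT", "HEART", "HIPPOC", "KIDNEY", "LIVER", "LUNG",
                   "PLASMA", "SKM-GN", "WAT-SC")
SEXES = ("male", "female")
GROUPS = ("SED", "1w", "2w", "4w", "8w")
TRAINING_GROUPS = GROUPS[1:]

GLOBAL_LOG2_BASE = 14.0
ISTD_LOG2_BASE = 15.0


@dataclass(frozen=True)
class StudyDesign:
    """Tissues x sexes x groups x n-per-cell layout; animal ids shared
    across tissues."""

    tissues: tuple = DEFAULT_TISSUES
    sexes: tuple = SEXES
    groups: tuple = GROUPS
    n_per_cell: int = 5
    seed: int = 0

    def animals(self) -> pd.DataFrame:
        rows = []
        i = 0
        for sex in self.sexes:
            for group in self.groups:
                for _ in range(self.n_per_cell):
                    rows.append({"animal_id": f"A{i:03d}", "sex": sex,
                                 "group": group})
                    i += 1
        return pd.DataFrame(rows).set_index("animal_id")


@dataclass(frozen=True)
class EffectSpec:
    """A planted effect on a selected lipid group.

    ``selector`` picks lipids by ``{"lipid_class": ...}``,
    ``{"classes": [...]}`` or ``{"ids": [...]}``. ``kind`` is
    ``sex_baseline`` (shift all groups of the listed sexes by ``size``),
    ``timewise`` (per-timepoint shifts vs SED, both sexes unless
    restricted), or ``sex_by_time`` (per-timepoint shifts in the listed
    sexes only — a sex-dimorphic training response). Sizes are standardized:
    multiples of the residual noise SD.
    """

    selector: Mapping
    kind: str
    sizes: Mapping[str, float] | float = 0.0
    sexes: tuple = SEXES
    tissues: Optional[tuple] = None
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("sex_baseline", "timewise", "sex_by_time"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        sizes = (self.sizes.values() if isinstance(self.sizes, Mapping)
                 else [self.sizes])
        if not all(np.isfinite(list(sizes))):
            raise ValueError("effect sizes must be finite")

    def resolve(self, universe: pd.DataFrame) -> list[str]:
        sel = self.selector
        if "ids" in sel:
            ids = [i for i in sel["ids"] if i in universe.index]
        elif "lipid_class" in sel:
            ids = list(universe.index[universe["lipid_class"] == sel["lipid_class"]])
        elif "classes" in sel:
            ids = list(universe.index[universe["lipid_class"].isin(sel["classes"])])
        else:
            raise ValueError(f"bad selector {sel!r}")
        ids = [i for i in ids if not universe.loc[i, "is_istd"]]
        if not ids:
            raise ValueError(f"selector {sel!r} resolves to zero lipids")
        return ids


@dataclass
class GroundTruth:
    """Everything planted: regenerable exactly from (design, effects, seed)."""

    group_means: dict                    # (tissue, sex) -> lipids x groups log2 means
    drift_slopes: dict                   # (tissue, mode) -> Series per feature
    planted_timewise: pd.DataFrame       # tissue, sex, timepoint, lipid, effect
    planted_sex_baseline: pd.DataFrame   # tissue, lipid, effect (male - female)
    qc_fail_features: dict               # (tissue, mode) -> {rule: [ids]}
    degenerate_names: pd.DataFrame       # name, keep_mode
    cluster_labels: dict                 # tissue -> Series lipid -> archetype
    module_labels: dict                  # tissue -> Series lipid -> block id
    phenotype_links: pd.DataFrame        # phenotype, tissue, block, gamma
    outlier_samples: dict                # (tissue, mode) -> [sample ids]
    noise_sd: float = 0.5


@dataclass
class SimulatedStudy:
    design: StudyDesign
    untargeted: dict                     # (tissue, mode) -> FeatureTable
    targeted: dict                       # tissue -> dict(conc, qc_conc, qc_rt)
    phenotypes: pd.DataFrame
    samples: pd.DataFrame                # sample_id -> animal_id, sex, group, tissue
    istd_concentrations: pd.Series       # istd feature id -> spiked conc (ug/mL)
    truth: GroundTruth
    universe: pd.DataFrame               # feature metadata incl. lipid_class


# ---------------------------------------------------------------------------
# Lipid universe
# ---------------------------------------------------------------------------

_CHAIN_POOL = ["14:0", "15:0", "16:0", "16:1", "17:0", "18:0", "18:1",
               "18:2", "18:3", "20:3", "20:4", "22:4", "22:5", "22:6"]

_ISTD_NAMES = {
    "PC": ("PC 15:0-18:1(d7)", "positive"),
    "LPC": ("LPC 18:1(d7)", "positive"),
    "PE": ("PE 15:0-18:1(d7)", "negative"),
    "LPE": ("LPE 18:1(d7)", "negative"),
    "PS": ("PS 15:0-18:1(d7)", "negative"),
    "PG": ("PG 15:0-18:1(d7)", "negative"),
    "PI": ("PI 15:0-18:1(d7)", "negative"),
    "DAG": ("DAG 15:0-18:1(d7)", "positive"),
    "TAG": ("TAG 15:0-18:1(d7)-15:0", "positive"),
    "SM": ("SM 18:1(d9)", "positive"),
    "CE": ("Chol Ester 18:1(d7)", "positive"),
}

# class -> (ISTD class used, own/fallback). Classes without their own spiked
# standard borrow the closest available one in the same ESI mode, as
# explicit configuration.
ISTD_FALLBACKS = {
    "O-PC": "PC", "O-PE": "PE", "Cer": "PE", "HexCer": "PE",
    "Car": "LPC", "NAE": "LPC", "FFA": "LPE", "SiE": "CE",
}

_CLASS_MODE = {
    "TAG": "positive", "PC": "positive", "O-PC": "positive", "LPC": "positive",
    "DAG": "positive", "SM": "positive", "Car": "positive", "CE": "positive",
    "SiE": "positive", "NAE": "positive",
    "PE": "negative", "O-PE": "negative", "PS": "negative", "PG": "negative",
    "PI": "negative", "LPE": "negative", "Cer": "negative",
    "HexCer": "negative", "FFA": "negative",
}


def _tag_names(rng, n):
    names = set()
    while len(names) < n:
        c = int(rng.integers(30, 61))
        d = int(rng.integers(0, min(9, max(2, (c - 28) // 3))))
        names.add(f"TAG {c}:{d}")
    return sorted(names)


def _two_chain_names(rng, cls, n, pool=None):
    pool = pool or _CHAIN_POOL
    names = set()
    while len(names) < n:
        a, b = rng.choice(pool, size=2, replace=True)
        names.add(f"{cls} {a}_{b}")
    return sorted(names)


def _one_chain_names(rng, cls, n, pool=None):
    pool = pool or _CHAIN_POOL
    names = {f"{cls} {c}" for c in rng.choice(pool, size=min(n, len(pool)),
                                              replace=False)}
    extra = ["20:0", "22:0", "24:0", "24:1", "26:0"]
    for c in extra:
        if len(names) >= n:
            break
        names.add(f"{cls} {c}")
    return sorted(names)


_CLASS_PLAN = (
    ("TAG", 140, _tag_names),
    ("PC", 95, lambda rng, n: _two_chain_names(rng, "PC", n)),
    ("PE", 55, lambda rng, n: _two_chain_names(rng, "PE", n)),
    ("O-PE", 25, lambda rng, n: [f"PE O-{a}_{b}"
                                 for a, b in {tuple(rng.choice(_CHAIN_POOL, 2))
                                              for _ in range(4 * n)}][:n]),
    ("O-PC", 12, lambda rng, n: [f"PC O-{a}_{b}"
                                 for a, b in {tuple(rng.choice(_CHAIN_POOL, 2))
                                              for _ in range(4 * n)}][:n]),
    ("PS", 14, lambda rng, n: _two_chain_names(rng, "PS", n)),
    ("PG", 12, lambda rng, n: _two_chain_names(rng, "PG", n)),
    ("PI", 12, lambda rng, n: _two_chain_names(rng, "PI", n)),
    ("LPC", 22, lambda rng, n: _one_chain_names(rng, "LPC", n)),
    ("LPE", 12, lambda rng, n: _one_chain_names(rng, "LPE", n)),
    ("DAG", 25, lambda rng, n: _two_chain_names(rng, "DAG", n)),
    ("SM", 28, lambda rng, n: sorted({f"SM d{int(rng.integers(30, 45))}:"
                                      f"{int(rng.integers(0, 4))}"
                                      for _ in range(6 * n)})[:n]),
    ("Cer", 22, lambda rng, n: sorted({f"Cer C{int(rng.integers(14, 27))}:"
                                       f"{int(rng.integers(0, 2))}"
                                       for _ in range(6 * n)})[:n]),
    ("HexCer", 14, lambda rng, n: sorted({f"HexCer d{int(rng.integers(32, 45))}:"
                                          f"{int(rng.integers(1, 3))}"
                                          for _ in range(6 * n)})[:n]),
    ("Car", 18, lambda rng, n: _one_chain_names(rng, "Car", n)),
    ("CE", 10, lambda rng, n: _one_chain_names(rng, "CE", n)),
    ("SiE", 3, lambda rng, n: _one_chain_names(rng, "SiE", n)),
    ("FFA", 24, lambda rng, n: _one_chain_names(rng, "FFA", n)),
    ("NAE", 10, lambda rng, n: _one_chain_names(rng, "NAE", n)),
)

# log2 class-by-tissue baseline offsets (selected rows; default 0).
# TAG dominance in the adipose depots drives the class-composition profile;
# ether-PE and HexCer enrichment marks the hippocampus.
_CLASS_TISSUE_OFFSET = {
    ("TAG", "WAT-SC"): 7.5, ("TAG", "BAT"): 7.0, ("TAG", "LIVER"): 3.0,
    ("TAG", "SKM-GN"): 2.5, ("TAG", "HEART"): 2.0, ("TAG", "HIPPOC"): -2.0,
    ("O-PE", "HIPPOC"): 4.0, ("O-PE", "HEART"): 2.0,
    ("HexCer", "HIPPOC"): 4.0,
    ("PC", "LIVER"): 2.0, ("PC", "LUNG"): 2.0, ("PC", "HEART"): 1.5,
    ("PC", "SKM-GN"): 1.5,
    ("LPC", "PLASMA"): 2.0, ("CE", "PLASMA"): 2.0,
    ("Car", "HEART"): 1.5, ("Car", "LIVER"): 1.0,
}


def build_lipid_universe(rng: np.random.Generator,
                         n_unknown: int = 15) -> pd.DataFrame:
    """Feature metadata table: id, name, class, mode, MSI level, ISTD flag.

    Names are drawn from per-class shorthand generators and validated by the
    nomenclature parser; a small MSI-4 (unannotated) tail and one spiked
    internal standard per class/mode are appended.
    """
    rows = []
    used = set()
    for cls, n, gen in _CLASS_PLAN:
        for name in gen(rng, n):
            if name in used:
                continue
            used.add(name)
            ann = parse_lipid_name(name)
            rows.append({"name": name, "lipid_class": ann.lipid_class,
                         "esi_mode": _CLASS_MODE[cls],
                         "msi_level": int(rng.choice([1, 2, 2, 3])),
                         "is_istd": False})
    for i in range(n_unknown):
        rows.append({"name": f"Unknown_{i:03d}", "lipid_class": None,
                     "esi_mode": "positive" if i % 2 == 0 else "negative",
                     "msi_level": 4, "is_istd": False})
    for cls, (name, mode) in _ISTD_NAMES.items():
        rows.append({"name": name, "lipid_class": cls, "esi_mode": mode,
                     "msi_level": 1, "is_istd": True})
    df = pd.DataFrame(rows)
    df.index = [f"F{i:04d}" for i in range(len(df))]
    df.index.name = "feature_id"
    return df


def default_effect_specs(noise_sd: float = 0.5) -> list[EffectSpec]:
    """Planted study conditions: the qualitative patterns the analysis is
    designed to detect, at standardized sizes detectable with n=5."""
    return [
        # females carry more ether-PE and SM at baseline
        EffectSpec({"classes": ["O-PE", "SM"]}, "sex_baseline", sizes=-2.0,
                   sexes=("male",), label="female_high_etherPE_SM"),
        # adipose/muscle TAG: early depletion, partial rebound by 8w
        EffectSpec({"lipid_class": "TAG"}, "timewise",
                   sizes={"1w": -3.0, "2w": -3.0, "4w": -1.5, "8w": -0.5},
                   tissues=("WAT-SC", "BAT", "SKM-GN"), label="tag_depletion"),
        # acylcarnitines rise in oxidative tissues
        EffectSpec({"lipid_class": "Car"}, "timewise",
                   sizes={"1w": 2.0, "2w": 3.0, "4w": 3.0, "8w": 2.0},
                   tissues=("HEART", "LIVER"), label="car_rise"),
        # hippocampal hexosylceramides decline late
        EffectSpec({"lipid_class": "HexCer"}, "timewise",
                   sizes={"1w": 0.0, "2w": -1.0, "4w": -2.0, "8w": -3.0},
                   tissues=("HIPPOC",), label="hexcer_decline"),
        # male-only heart phospholipid remodeling (sex-dimorphic response)
        EffectSpec({"classes": ["PC", "PE"]}, "sex_by_time",
                   sizes={"1w": 1.0, "2w": 2.0, "4w": 3.0, "8w": 3.0},
                   sexes=("male",), tissues=("HEART",),
                   label="male_heart_phospholipid"),
    ]


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

_PHENOTYPES = ("body_weight", "pct_fat", "pct_lean", "nefa", "glycerol",
               "glucose", "leptin", "vo2max", "max_run_speed",
               "adipocyte_area", "adipocyte_count")

# per-sex (base, per-group-index trend) temporal templates
_PHENO_TEMPLATES = {
    "body_weight": {"male": (380.0, -4.0), "female": (225.0, -1.5)},
    "pct_fat": {"male": (20.0, -1.5), "female": (15.0, -0.5)},
    "pct_lean": {"male": (72.0, 1.2), "female": (77.0, 0.4)},
    "glucose": {"male": (160.0, -3.0), "female": (140.0, -1.5)},
    "leptin": {"male": (6.0, -0.8), "female": (3.0, -0.2)},
    "vo2max": {"male": (65.0, 2.5), "female": (70.0, 2.0)},
    "max_run_speed": {"male": (25.0, 1.5), "female": (28.0, 1.2)},
    "adipocyte_area": {"male": (4000.0, -300.0), "female": (2500.0, -100.0)},
    "adipocyte_count": {"male": (180.0, 8.0), "female": (210.0, 4.0)},
}
# rise-then-fall circulating substrates (per-group-index profile)
_RISE_FALL = {"nefa": (0.45, (0.0, 0.20, 0.25, 0.12, 0.03)),
              "glycerol": (0.30, (0.0, 0.10, 0.14, 0.06, 0.02))}

_TARGETED_ANALYTES = (
    "PGE2", "PGD2", "TXB2", "LTB4", "5-HETE", "12-HETE", "15-HETE",
    "20-HETE", "9-HODE", "13-HODE", "9,10-DiHOME", "12,13-DiHOME",
    "14,15-DiHETrE", "17-HDHA", "AEA", "OEA", "PEA", "DHEA", "LEA", "SEA",
)


def _assign_presence(rng, universe, tissues):
    """Per-tissue feature presence: shared core plus tissue-specific dropout."""
    presence = {}
    core = rng.random(len(universe)) < 0.7
    for tissue in tissues:
        drop = rng.random(len(universe)) < 0.15
        keep = core | ~drop
        keep = keep | universe["is_istd"].to_numpy()  # ISTDs always spiked
        presence[tissue] = pd.Series(keep, index=universe.index)
    return presence


def simulate_study(
    design: StudyDesign = StudyDesign(),
    effects: Optional[Sequence[EffectSpec]] = None,
    noise_sd: float = 0.5,
    missing_rate: float = 0.05,
    drift_sd: float = 0.08,
    module_strength: float = 0.5,
    qc_interval: int = 10,
    n_blanks: int = 3,
    planted_outliers: int = 0,
    seed: Optional[int] = None,
) -> SimulatedStudy:
    """Generate a complete synthetic study with ground truth.

    ``effects=None`` plants the default study conditions
    (:func:`default_effect_specs`); pass ``effects=[]`` for a null study.
    ``planted_outliers`` shifts that many study samples (one per affected
    table) far off-profile to exercise outlier screening.
    ``module_strength`` scales the per-animal latent factors behind the
    planted co-expression blocks; it trades module detectability against
    extra animal-level variance on the block lipids.
    """
    if not (0 <= missing_rate < 0.5):
        raise ValueError("missing_rate must be in [0, 0.5)")
    if effects is None:
        effects = default_effect_specs(noise_sd)
    rng = np.random.default_rng(design.seed if seed is None else seed)

    universe = build_lipid_universe(rng)
    lipids = universe.index
    n_feat = len(universe)
    animals = design.animals()
    presence = _assign_presence(rng, universe, design.tissues)

    # fixed lipid-specific offsets and tissue jitter; the wide baseline
    # spread (several orders of magnitude on the area scale) is what makes
    # raw-intensity inter-sample correlations high, as in real feature tables
    lipid_offset = pd.Series(np.clip(rng.normal(0.0, 2.5, n_feat), -4.0, 4.0),
                             index=lipids)
    tissue_jitter = {t: pd.Series(rng.normal(0.0, 0.4, n_feat), index=lipids)
                     for t in design.tissues}

    # co-expression blocks: per tissue, a TAG block and a phospholipid block
    module_labels = {}
    block_members: dict[tuple, dict[int, list]] = {}
    for tissue in design.tissues:
        tag_ids = [f for f in lipids
                   if universe.loc[f, "lipid_class"] == "TAG"
                   and presence[tissue][f]][:40]
        pl_ids = [f for f in lipids
                  if universe.loc[f, "lipid_class"] in ("PC", "PE")
                  and presence[tissue][f]][:30]
        labels = pd.Series(0, index=lipids, dtype=int)
        labels[tag_ids] = 1
        labels[pl_ids] = 2
        module_labels[tissue] = labels
        block_members[tissue] = {1: tag_ids, 2: pl_ids}
    block_lambda = {1: module_strength, 2: 0.8 * module_strength}

    # per-animal, per-tissue latent block factors
    z = {(t, b): pd.Series(rng.normal(0.0, 1.0, len(animals)),
                           index=animals.index)
         for t in design.tissues for b in (1, 2)}

    # resolve effects once
    resolved = []
    for spec in effects:
        ids = spec.resolve(universe)
        resolved.append((spec, set(ids)))

    # true group means (log2, before latent/noise), per tissue x sex
    group_means = {}
    planted_tw, planted_sb = [], []
    cluster_labels = {}
    noise_scale = {}
    for tissue in design.tissues:
        pres = presence[tissue]
        base = (GLOBAL_LOG2_BASE + lipid_offset + tissue_jitter[tissue]
                + universe["lipid_class"].map(
                    lambda c: _CLASS_TISSUE_OFFSET.get((c, tissue), 0.0)
                    if c is not None else 0.0))
        # intensity-dependent precision: abundant features are measured with
        # lower relative noise, as on a real instrument; the same factor
        # scales the latent block loadings so standardized-scale structure
        # (and hence module detectability) is intensity-invariant
        noise_scale[tissue] = pd.Series(
            0.5 + 0.5 / (1.0 + np.exp((base - base.median()) / 1.5)),
            index=lipids)
        clabels = pd.Series("none", index=lipids, dtype=object)
        for sex in design.sexes:
            mu = pd.DataFrame({g: base.copy() for g in design.groups})
            for spec, ids in resolved:
                if spec.tissues is not None and tissue not in spec.tissues:
                    continue
                sel = [f for f in ids if pres[f]]
                if spec.kind == "sex_baseline":
                    if sex in spec.sexes:
                        mu.loc[sel, :] += float(spec.sizes) * noise_sd
                        if sex == design.sexes[0]:
                            for f in sel:
                                planted_sb.append({
                                    "tissue": tissue, "lipid": f,
                                    "effect": float(spec.sizes) * noise_sd})
                else:
                    if sex not in spec.sexes:
                        continue
                    for tp, size in spec.sizes.items():
                        if size == 0.0:
                            continue
                        mu.loc[sel, tp] += size * noise_sd
                        for f in sel:
                            planted_tw.append({
                                "tissue": tissue, "sex": sex,
                                "timepoint": tp, "lipid": f,
                                "effect": size * noise_sd,
                                "label": spec.label})
                    if sex == spec.sexes[0]:
                        clabels[sel] = spec.label or spec.kind
            group_means[(tissue, sex)] = mu
        cluster_labels[tissue] = clabels

    # sample table
    sample_rows = []
    for tissue in design.tissues:
        for aid, arow in animals.iterrows():
            sample_rows.append({
                "sample_id": f"{tissue}_{aid}", "animal_id": aid,
                "sex": arow["sex"], "group": arow["group"], "tissue": tissue})
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    istd_conc = pd.Series(
        {fid: float(np.round(rng.uniform(0.5, 8.0), 2))
         for fid in universe.index[universe["is_istd"]]}, name="conc_ug_ml")

    # planted QC failures and cross-mode degenerates
    annotated = universe.index[(universe["msi_level"] <= 3)
                               & ~universe["is_istd"]]
    degen_pool = [f for f in annotated
                  if universe.loc[f, "lipid_class"] in ("PE", "PS", "PG")][:8]
    degenerate = pd.DataFrame({
        "name": universe.loc[degen_pool, "name"].to_list(),
        "keep_mode": "negative",   # twin in positive mode is made noisier
    })

    untargeted = {}
    drift_slopes = {}
    qc_fail = {}
    outlier_samples = {}
    truth_noise = noise_sd

    for tissue in design.tissues:
        pres = presence[tissue]
        for mode in ("positive", "negative"):
            in_mode = (universe["esi_mode"] == mode) & pres
            feats = universe.index[in_mode].to_list()
            twin_ids = []
            if mode == "positive":
                # degenerate twins: negative-mode species also seen in positive
                twin_ids = [f"{f}_pos" for f in degen_pool if pres[f]]
                feats = feats + twin_ids
            n_f = len(feats)

            tissue_samples = samples[samples["tissue"] == tissue]
            sids = tissue_samples.index.to_list()
            n_s = len(sids)

            # injection layout: blank, QC, blocks of study with periodic QCs
            order_rows = []
            pos = 1
            order_rows.append(("blank", None)); pos += 1
            study_iter = iter(rng.permutation(sids))
            placed = 0
            order_rows.append(("QC", None))
            while placed < n_s:
                for _ in range(qc_interval - 1):
                    try:
                        sid = next(study_iter)
                    except StopIteration:
                        break
                    order_rows.append(("study", sid))
                    placed += 1
                order_rows.append(("QC", None))
            for _ in range(n_blanks - 1):
                order_rows.append(("blank", None))
            inj = pd.DataFrame({
                "order": np.arange(1, len(order_rows) + 1),
                "role": [r for r, _ in order_rows],
                "sample_id": [s for _, s in order_rows],
            }, index=[f"{tissue[:3]}{mode[:3]}_inj{i:03d}"
                      for i in range(len(order_rows))])

            # log2 study values
            logx = np.empty((n_f, n_s))
            base_ids = [f[:-4] if f.endswith("_pos") else f for f in feats]
            for j, sid in enumerate(sids):
                srow = tissue_samples.loc[sid]
                mu = group_means[(tissue, srow["sex"])][srow["group"]]
                vals = mu[base_ids].to_numpy(float).copy()
                cf = noise_scale[tissue][base_ids].to_numpy(float)
                for b in (1, 2):
                    members = set(block_members[tissue][b])
                    mask = np.array([f in members for f in base_ids])
                    vals[mask] += (block_lambda[b] * cf[mask]
                                   * z[(tissue, b)][srow["animal_id"]])
                vals += rng.normal(0.0, 1.0, n_f) * truth_noise * cf
                logx[:, j] = vals
            is_istd_vec = universe.loc[base_ids, "is_istd"].to_numpy(bool)
            logx[is_istd_vec, :] = (ISTD_LOG2_BASE
                                    + rng.normal(0.0, 0.05,
                                                 (is_istd_vec.sum(), n_s)))

            # planted QC failures (annotated, non-ISTD, non-twin features)
            eligible = [f for f in feats
                        if not f.endswith("_pos")
                        and not universe.loc[f, "is_istd"]
                        and universe.loc[f, "msi_level"] <= 3
                        and module_labels[tissue].get(f, 0) == 0
                        and f not in degen_pool]
            rng.shuffle(eligible)
            bg_ids = eligible[:6]
            hicv_ids = eligible[6:10]
            qc_fail[(tissue, mode)] = {"blank_ratio": sorted(bg_ids),
                                       "qc_cv": sorted(hicv_ids)}

            # pooled-QC log2 values: mean of study pool + injection noise
            pool = logx.mean(axis=1)
            qc_idx = inj.index[inj["role"] == "QC"]
            n_qc = len(qc_idx)
            qc_noise = rng.normal(0.0, 0.08, (n_f, n_qc))
            for f in hicv_ids:
                i = feats.index(f)
                # unambiguous planted failure: expected CV far above 30%
                qc_noise[i, :] = rng.normal(0.0, 1.5, n_qc)
            qclog = pool[:, None] + qc_noise

            # degenerate twins: same analyte, noisier in positive mode
            for tid in twin_ids:
                src = tid[:-4]
                i = feats.index(tid)
                qclog[i, :] += rng.normal(0.0, 0.6, n_qc)

            # blanks: tiny background, except planted background features
            blank_idx = inj.index[inj["role"] == "blank"]
            blog = np.full((n_f, len(blank_idx)), 2.0)
            blog += rng.normal(0.0, 0.3, blog.shape)
            study_mean = logx.mean(axis=1)
            for f in bg_ids:
                i = feats.index(f)
                blog[i, :] = study_mean[i] - 1.0  # blank ~ study/2 (< 5x rule)

            # planted outlier samples
            out_ids = []
            if planted_outliers > 0:
                picks = rng.choice(n_s, size=planted_outliers, replace=False)
                for jj in picks:
                    logx[:, jj] += 20.0 * truth_noise
                    out_ids.append(sids[jj])
            outlier_samples[(tissue, mode)] = out_ids

            # intensity-dependent missingness on study cells (ISTDs exempt)
            if missing_rate > 0:
                zscore = (logx - logx.mean()) / (logx.std() + 1e-9)
                p = 1.0 / (1.0 + np.exp(zscore / 0.8))
                p *= missing_rate / max(p.mean(), 1e-9)
                p = np.clip(p, 0.0, 0.95)
                miss = rng.random(p.shape) < p
                miss[is_istd_vec, :] = False
                logx = np.where(miss, np.nan, logx)

            # drift: multiplicative linear factor along injection order
            slopes = rng.normal(0.0, drift_sd, n_f)
            orders = inj["order"].to_numpy(float)
            ref = np.median(orders)
            span = orders.max()
            factor = 1.0 + slopes[:, None] * (orders[None, :] - ref) / span
            factor = np.clip(factor, 0.05, None)

            areas = np.full((n_f, len(inj)), np.nan)
            study_mask = inj["role"].to_numpy() == "study"
            # logx columns follow `sids`; injections carry a randomized order
            inj_sids = inj.loc[study_mask, "sample_id"].to_list()
            col_of = {sid: j for j, sid in enumerate(sids)}
            areas[:, study_mask] = 2.0 ** logx[:, [col_of[s] for s in inj_sids]]
            areas[:, inj["role"].to_numpy() == "QC"] = 2.0 ** qclog
            areas[:, inj["role"].to_numpy() == "blank"] = 2.0 ** blog
            areas *= factor

            fmeta = universe.loc[base_ids, ["name", "msi_level", "esi_mode",
                                            "is_istd", "lipid_class"]].copy()
            fmeta.index = feats
            fmeta["esi_mode"] = mode
            table = FeatureTable(
                areas=pd.DataFrame(areas, index=feats, columns=inj.index),
                features=fmeta, injections=inj, tissue=tissue, esi_mode=mode)
            untargeted[(tissue, mode)] = table
            drift_slopes[(tissue, mode)] = pd.Series(slopes, index=feats)

    # phenotypes: temporal templates + linkage to the WAT-SC TAG block
    gidx = {g: i for i, g in enumerate(design.groups)}
    pheno_rows = {}
    link_tissue = "WAT-SC" if "WAT-SC" in design.tissues else design.tissues[0]
    zlink = z[(link_tissue, 1)]
    gammas = {"pct_fat": 1.2, "leptin": 0.8, "adipocyte_area": 150.0,
              "nefa": 0.05}
    for aid, arow in animals.iterrows():
        sex, g = arow["sex"], gidx[arow["group"]]
        row = {}
        for name, per_sex in _PHENO_TEMPLATES.items():
            base_v, trend = per_sex[sex]
            row[name] = base_v + trend * g + rng.normal(0, abs(base_v) * 0.03)
        for name, (base_v, profile) in _RISE_FALL.items():
            row[name] = base_v + profile[g] + rng.normal(0, base_v * 0.08)
        for name, gamma in gammas.items():
            row[name] += gamma * zlink[aid]
        pheno_rows[aid] = row
    phenotypes = pd.DataFrame.from_dict(pheno_rows, orient="index")
    phenotypes = animals.join(phenotypes)
    phenotype_links = pd.DataFrame(
        [{"phenotype": k, "tissue": link_tissue, "block": 1, "gamma": v}
         for k, v in gammas.items()])

    # targeted assay: concentrations with QC replicates, planted failures
    targeted = {}
    for tissue in design.tissues:
        tissue_samples = samples[samples["tissue"] == tissue]
        sids = tissue_samples.index.to_list()
        base_t = rng.uniform(0.5, 30.0, len(_TARGETED_ANALYTES))
        conc = np.empty((len(_TARGETED_ANALYTES), len(sids)))
        for j, sid in enumerate(sids):
            srow = tissue_samples.loc[sid]
            shift = np.zeros(len(_TARGETED_ANALYTES))
            # a couple of training-responsive oxylipins
            if srow["group"] != "SED":
                shift[:3] = 0.6
            conc[:, j] = base_t * np.exp(rng.normal(0, 0.35,
                                                    len(base_t)) + shift)
        # missingness; analyte 4 pushed past the 20% filter
        miss = rng.random(conc.shape) < 0.05
        miss[4, : max(1, int(0.3 * len(sids)))] = True
        conc = np.where(miss, np.nan, conc)
        qc_conc = base_t[:, None] * np.exp(rng.normal(0, 0.1,
                                                      (len(base_t), 6)))
        qc_conc[2, :] = base_t[2] * np.exp(rng.normal(0, 1.5, 6))  # CV > 100%
        rt = rng.uniform(1.0, 12.0, len(base_t))
        qc_rt = rt[:, None] * (1 + rng.normal(0, 0.01, (len(base_t), 6)))
        qc_rt[3, :] = rt[3] * (1 + rng.normal(0, 0.25, 6))         # RT CV > 10%
        idx = list(_TARGETED_ANALYTES)
        targeted[tissue] = {
            "conc": pd.DataFrame(conc, index=idx, columns=sids),
            "qc_conc": pd.DataFrame(qc_conc, index=idx,
                                    columns=[f"QC{i}" for i in range(6)]),
            "qc_rt": pd.DataFrame(qc_rt, index=idx,
                                  columns=[f"QC{i}" for i in range(6)]),
        }

    truth = GroundTruth(
        group_means=group_means,
        drift_slopes=drift_slopes,
        planted_timewise=pd.DataFrame(
            planted_tw, columns=["tissue", "sex", "timepoint", "lipid",
                                 "effect", "label"]),
        planted_sex_baseline=pd.DataFrame(
            planted_sb, columns=["tissue", "lipid", "effect"]),
        qc_fail_features=qc_fail,
        degenerate_names=degenerate,
        cluster_labels=cluster_labels,
        module_labels=module_labels,
        phenotype_links=phenotype_links,
        outlier_samples=outlier_samples,
        noise_sd=noise_sd,
    )
    return SimulatedStudy(
        design=design, untargeted=untargeted, targeted=targeted,
        phenotypes=phenotypes, samples=samples,
        istd_concentrations=istd_conc, truth=truth, universe=universe)


def simulate_normalized_matrix(
    n_lipids: int = 2000,
    n_per_cell: int = 5,
    groups: Sequence[str] = GROUPS,
    effects: Optional[Mapping[str, Mapping[str, float]]] = None,
    noise_sd: float = 0.5,
    seed: Optional[int] = None,
):
    """Direct lipids-by-samples log2 matrix for statistical experiments.

    Bypasses the instrument layer (no drift, QC injections or missingness):
    each cell is the group mean plus Gaussian noise, which is the
    differential stage's input contract. ``effects`` maps lipid id ->
    {timepoint: standardized effect size}; lipid ids are ``L0000``-style
    and any id not in ``effects`` is null. Returns (matrix, meta, planted)
    where planted is a DataFrame (lipid, timepoint, effect in log2 units).
    """
    rng = np.random.default_rng(seed)
    lipids = [f"L{i:04d}" for i in range(n_lipids)]
    sample_rows = []
    for g in groups:
        for i in range(n_per_cell):
            sample_rows.append({"sample_id": f"{g}_{i}", "group": g})
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    mu = pd.DataFrame(0.0, index=lipids, columns=meta.index)
    planted = []
    for lip, sizes in (effects or {}).items():
        for tp, size in sizes.items():
            cols = meta.index[meta["group"] == tp]
            mu.loc[lip, cols] += size * noise_sd
            planted.append({"lipid": lip, "timepoint": tp,
                            "effect": size * noise_sd})
    matrix = mu + rng.normal(0.0, noise_sd, mu.shape)
    matrix -= matrix.median(axis=0)          # sample median-centering
    return matrix, meta, pd.DataFrame(planted,
                                      columns=["lipid", "timepoint", "effect"])


def truth_report(truth: GroundTruth, results: pd.DataFrame,
                 fdr: float = 0.05,
                 allow_missing: bool = False) -> tuple[float, float]:
    """(sensitivity, empirical FDR) of timewise discoveries against truth.

    ``results`` must carry columns tissue, sex, timepoint, lipid, adj_p and
    cover every lipid the truth plants (same universe per tissue/sex).
    Sensitivity is recovered/planted; empirical FDR is false
    discoveries/discoveries, 0 when there are no discoveries. With
    ``allow_missing`` planted lipids absent from the results (e.g. removed
    by upstream QC) are dropped from the denominator instead of raising.
    """
    req = {"tissue", "sex", "timepoint", "lipid", "adj_p"}
    if not req <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(req)}")
    key = ["tissue", "sex", "timepoint", "lipid"]
    planted = truth.planted_timewise
    covered = set(results["lipid"])
    missing = set(planted["lipid"]) - covered
    if missing and not allow_missing:
        raise ValueError(
            f"results do not cover {len(missing)} planted lipids "
            f"(e.g. {sorted(missing)[:3]})")
    if missing:
        planted = planted[planted["lipid"].isin(covered)]
    planted_keys = set(map(tuple, planted[key].to_numpy()))
    disc = results[results["adj_p"] < fdr]
    disc_keys = set(map(tuple, disc[key].to_numpy()))
    if planted_keys:
        sensitivity = len(disc_keys & planted_keys) / len(planted_keys)
    else:
        sensitivity = 0.0
    if disc_keys:
        efdr = len(disc_keys - planted_keys) / len(disc_keys)
    else:
        efdr = 0.0
    return sensitivity, efdr
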