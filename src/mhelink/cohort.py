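"""Synthetic multi-omic cohort generator.

Emulates the data structure of a small cirrhosis cohort (6 patients with
minimal hepatic encephalopathy, MHE, and 5 without) profiled on three
layers: a blood gene-expression microarray, a targeted 143-metabolite
serum panel (Biocrates-style classes: acylcarnitines, amino acids,
biogenic amines, hexose, sphingomyelins, glycerophospholipids) and a
14-cytokine ELISA panel.

The generative model has three ingredients:

* per-feature baselines on the log2 scale with heterogeneous variances
  (gene variances drawn from a scaled-inverse-chi-square prior, matching
  the working model of the empirical-Bayes moderated t-test downstream);
* planted case-vs-control log2 fold changes (group effects);
* latent correlation modules: each module has a factor
  ``f_s = shift * 1[case_s] + u_s`` with ``u_s ~ N(0, 1)``; a member
  compound is ``baseline + sign * loading * f + noise`` so that the
  planted group effect of a member (``sign * loading * shift``) and its
  co-variation with the rest of the module arise from one mechanism.
  A configurable subset of planted genes is coupled to each module's
  factor, giving the downstream PLS models a recoverable signal.

Matrices are written on the measurement scale (intensities / uM / pg/ml,
i.e. ``2 ** log2value``); the analysis pipeline re-estimates the log scale
through its variance-stabilizing transform.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CASE, CONTROL, OmicsMatrix, write_groups

# Catalog baselines are a fixed property of the default panels, not of a
# particular cohort draw.
_CATALOG_SEED = 180_180


@dataclass(frozen=True)
class CohortDesign:
    """Sample-size design of a two-group cohort."""

    n_case: int = 6
    n_control: int = 5
    seed: int = 2021

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    def sample_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_samples)]

    def groups(self) -> pd.Series:
        labels = [CASE] * self.n_case + [CONTROL] * self.n_control
        return pd.Series(labels, index=self.sample_ids(), name="group")

    def case_indicator(self) -> np.ndarray:
        return np.array([1.0] * self.n_case + [0.0] * self.n_control)


@dataclass(frozen=True)
class PlantedEffect:
    """A case-vs-control log2 fold change planted on one feature."""

    feature_id: str
    log2fc: float


@dataclass
class ModuleMember:
    sign: int          # +1 / -1: orientation w.r.t. the module factor
    loading: float     # magnitude multiplying the factor
    noise_sd: float    # member-specific log2-scale noise


@dataclass
class LatentModuleSpec:
    """One latent correlation module of serum compounds.

    ``shift`` is the difference in factor mean between case and control
    samples (in units of the factor's within-group SD, which is 1).
    ``coupled`` maps gene ids to their factor coupling; a coupled gene's
    group effect is ``kappa * shift``.
    """

    name: str
    members: dict[str, ModuleMember] = field(default_factory=dict)
    shift: float = 2.5
    coupled: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Default feature catalogs
# ---------------------------------------------------------------------------

AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val",
]
BIOGENIC_AMINES = [
    "Ac-Orn", "ADMA", "alpha-AAA", "Carnosine", "Creatinine", "Histamine",
    "Kynurenine", "Met-SO", "Putrescine", "Sarcosine", "SDMA", "Serotonin",
    "Spermidine", "Spermine", "t4-OH-Pro", "Taurine", "total DMA",
]
ACYLCARNITINES = ["C0", "C2", "C3", "C4", "C8", "C10", "C16", "C18:2"]
SPHINGOMYELINS = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C22:3",
    "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1", "SM (OH) C14:1",
    "SM (OH) C16:1", "SM (OH) C22:1", "SM (OH) C22:2", "SM (OH) C24:1",
]
LYSO_PC = [f"lysoPC a {s}" for s in (
    "C14:0", "C16:0", "C16:1", "C17:0", "C18:0", "C18:1", "C18:2", "C20:3",
    "C20:4", "C24:0", "C26:0", "C26:1", "C28:0", "C28:1")]
PC_AA = [f"PC aa {s}" for s in (
    "C24:0", "C28:1", "C30:0", "C32:0", "C32:1", "C32:2", "C32:3", "C34:1",
    "C34:2", "C34:3", "C34:4", "C36:0", "C36:1", "C36:2", "C36:3", "C36:4",
    "C36:5", "C36:6", "C38:0", "C38:3", "C38:4", "C38:5", "C38:6", "C40:1",
    "C40:2", "C40:3", "C40:4", "C40:5", "C40:6", "C42:0", "C42:1", "C42:2",
    "C42:4", "C42:5", "C42:6")]
PC_AE = [f"PC ae {s}" for s in (
    "C30:0", "C30:1", "C30:2", "C32:1", "C32:2", "C34:0", "C34:1", "C34:2",
    "C34:3", "C36:0", "C36:1", "C36:2", "C36:3", "C36:4", "C36:5", "C38:0",
    "C38:1", "C38:2", "C38:3", "C38:4", "C40:1", "C40:2", "C40:3", "C40:4",
    "C42:1", "C42:2", "C42:3", "C42:5", "C44:3", "C44:4", "C44:5", "C44:6")]
GLYCEROPHOSPHOLIPIDS = LYSO_PC + PC_AA + PC_AE

CYTOKINES = [
    "IL-4", "IL-6", "IL-10", "IL-12", "IL-13", "IL-15", "IL-17", "IL-18",
    "IL-22", "CCL20", "CX3CL1", "CXCL13", "TGFb", "TNFa",
]

# Default planted serum effects: metabolite log2 fold changes (case minus
# control) of the compounds that separate MHE from non-MHE patients in the
# emulated study.
METABOLITE_EFFECTS: dict[str, float] = {
    "PC aa C36:4": -0.7436, "PC aa C38:4": -0.7106, "PC aa C38:5": -0.6788,
    "PC aa C40:5": -0.6272, "PC aa C34:4": -0.8185, "lysoPC a C20:4": -0.5669,
    "PC aa C40:6": -0.7801, "PC aa C38:6": -0.8598, "PC ae C38:0": -0.5767,
    "Met": 0.6004, "PC aa C36:5": -0.8773, "SM (OH) C14:1": 0.5611,
    "PC ae C44:6": 0.6000, "Spermine": -0.3971, "PC aa C38:3": -0.5105,
    "alpha-AAA": -0.4547, "PC aa C40:4": -0.4155, "PC aa C36:6": -0.6148,
    "lysoPC a C20:3": -0.6249, "PC aa C34:3": -0.5725, "Val": -0.4825,
    "SM C22:3": 1.1125, "PC aa C32:3": -0.3489, "PC aa C42:1": 0.3616,
    "SM C16:0": 0.3501, "PC ae C30:0": 0.4426, "PC ae C42:5": 0.5168,
    "PC ae C44:5": 0.5536, "C18:2": 0.4845,
}

# Cytokine control / case medians (pg/ml) for the six differential cytokines;
# the planted log2FC is log2(case / control).
CYTOKINE_MEDIANS: dict[str, tuple[float, float]] = {
    "IL-6": (1.15, 3.70), "IL-15": (4.66, 9.71), "IL-22": (56.04, 81.05),
    "CXCL13": (109.37, 194.48), "CCL20": (58.37, 90.20),
    "CX3CL1": (603.38, 833.42),
}
# Typical serum baselines (pg/ml) for the remaining panel cytokines.
_CYTOKINE_BASELINES = {
    "IL-4": 0.8, "IL-10": 3.1, "IL-12": 2.4, "IL-13": 2.5, "IL-17": 1.2,
    "IL-18": 150.0, "TGFb": 2100.0, "TNFa": 8.5,
}

_LIPID_RE = re.compile(r"C\s?(\d+):(\d+)")


def parse_lipid_composition(feature_id: str) -> tuple[int, int] | None:
    """Parse side-chain carbons and double bonds from 'C x:y' notation."""
    m = _LIPID_RE.search(feature_id)
    if m is None:
        return None
    return int(m.group(1)), int(m.group(2))


def default_metabolite_effects() -> list[PlantedEffect]:
    return [PlantedEffect(k, v) for k, v in METABOLITE_EFFECTS.items()]


def default_cytokine_effects() -> list[PlantedEffect]:
    return [PlantedEffect(k, float(np.log2(case / ctrl)))
            for k, (ctrl, case) in CYTOKINE_MEDIANS.items()]


def default_metabolite_catalog() -> pd.DataFrame:
    """143-metabolite serum panel catalog with class composition 8/21/17/1/15/81.

    Columns: id, omic, feature_class, carbons, double_bonds, baseline_log2
    (log2 uM), sd_log2 (baseline biological variation for features outside
    any latent module).
    """
    rng = np.random.default_rng(_CATALOG_SEED)
    rows = []
    ranges = {
        "acylcarnitine": (2.0, 5.0), "amino acid": (5.0, 8.0),
        "biogenic amine": (2.0, 5.0), "hexose": (12.2, 12.4),
        "sphingomyelin": (4.0, 7.0), "glycerophospholipid": (4.0, 8.0),
    }
    classes = [
        ("acylcarnitine", ACYLCARNITINES),
        ("amino acid", AMINO_ACIDS),
        ("biogenic amine", BIOGENIC_AMINES),
        ("hexose", ["H1"]),
        ("sphingomyelin", SPHINGOMYELINS),
        ("glycerophospholipid", GLYCEROPHOSPHOLIPIDS),
    ]
    for cls, ids in classes:
        lo, hi = ranges[cls]
        for fid in ids:
            comp = parse_lipid_composition(fid) if cls in (
                "acylcarnitine", "sphingomyelin", "glycerophospholipid") else None
            rows.append({
                "id": fid, "omic": "metabolite", "feature_class": cls,
                "carbons": comp[0] if comp else np.nan,
                "double_bonds": comp[1] if comp else np.nan,
                "baseline_log2": rng.uniform(lo, hi),
                "sd_log2": rng.uniform(0.10, 0.25),
            })
    cat = pd.DataFrame(rows)
    if cat["id"].duplicated().any():
        raise AssertionError("duplicate metabolite ids in default catalog")
    return cat


def default_cytokine_catalog() -> pd.DataFrame:
    rng = np.random.default_rng(_CATALOG_SEED + 1)
    rows = []
    for fid in CYTOKINES:
        if fid in CYTOKINE_MEDIANS:
            base = float(np.log2(CYTOKINE_MEDIANS[fid][0]))
        else:
            base = float(np.log2(_CYTOKINE_BASELINES[fid]))
        rows.append({
            "id": fid, "omic": "cytokine", "feature_class": "cytokine",
            "carbons": np.nan, "double_bonds": np.nan,
            "baseline_log2": base, "sd_log2": rng.uniform(0.15, 0.30),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "n_case", "n_control", "seed", "n_genes", "n_gene_effects",
    "gene_effect_range", "gene_baseline_range", "variance_prior",
    "n_coupled_per_module", "metabolite_shift", "cytokine_shift",
    "metabolite_noise_scale", "cytokine_noise_scale",
    "background_coupling_range", "null_cohort",
}


@dataclass
class CohortConfig:
    """Full configuration of a synthetic cohort.

    Defaults reproduce the emulated study design: 11 samples (6 MHE /
    5 control), 143 metabolites with 29 planted effects, 14 cytokines with
    6 planted effects, 847 planted gene effects, and 6 latent modules
    (one cytokine module, four lipid modules defined by side-chain
    carbon/double-bond rules, one small-molecule module).
    """

    n_case: int = 6
    n_control: int = 5
    seed: int = 2021
    n_genes: int = 5000
    n_gene_effects: int = 847
    gene_effect_range: tuple[float, float] = (0.8, 2.0)
    gene_baseline_range: tuple[float, float] = (6.0, 14.0)
    variance_prior: tuple[float, float] = (4.0, 0.05)  # (d0, s0^2)
    n_coupled_per_module: int = 25
    metabolite_shift: float = 2.5
    cytokine_shift: float = 3.5
    metabolite_noise_scale: float = 0.05
    cytokine_noise_scale: float = 0.05
    background_coupling_range: tuple[float, float] = (0.15, 0.30)
    null_cohort: bool = False  # no planted effects, no latent modules

    def design(self) -> CohortDesign:
        return CohortDesign(self.n_case, self.n_control, self.seed)

    @staticmethod
    def from_dict(d: dict) -> "CohortConfig":
        unknown = set(d) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(
                f"unknown synthetic-config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("gene_effect_range", "gene_baseline_range",
                    "variance_prior", "background_coupling_range"):
            if key in d:
                d[key] = tuple(d[key])
        return CohortConfig(**d)

    @staticmethod
    def from_file(path: str | Path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        return CohortConfig.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("gene_effect_range", "gene_baseline_range",
                    "variance_prior", "background_coupling_range"):
            d[key] = list(d[key])
        return d


def full_scale_config(seed: int = 2021) -> CohortConfig:
    """Configuration mirroring an 8x60K expression array (60,000 genes)."""
    return CohortConfig(seed=seed, n_genes=60000)


# ---------------------------------------------------------------------------
# Default latent modules
# ---------------------------------------------------------------------------

def _lipid_module_rule(fid: str) -> str | None:
    comp = parse_lipid_composition(fid)
    if comp is None or not (fid.startswith("PC") or fid.startswith("lysoPC")):
        return None
    carbons, dbs = comp
    if carbons > 40:
        return "M4_long_lipids"
    if dbs > 5:
        return "M3_short_polyunsaturated"
    if fid.startswith("PC aa"):
        return "M2_pc_diacyl_short"
    return "M6_pc_acylalkyl_lyso_short"


def default_modules(config: CohortConfig | None = None,
                    metabolite_effects: list[PlantedEffect] | None = None,
                    cytokine_effects: list[PlantedEffect] | None = None,
                    ) -> list[LatentModuleSpec]:
    """Build the six default latent modules from the planted serum effects.

    Module 1 holds the six differential cytokines; the lipids split into
    three modules by side-chain mass/saturation (>40 carbons; <=40 carbons
    with >5 double bonds; <=40 carbons with <=5 double bonds, the last
    divided into diacyl-PC vs acyl-alkyl-PC/lysoPC groups); remaining small
    molecules and sphingomyelins form the sixth module.  Member loadings
    are derived from the planted log2FCs so that
    ``sign * loading * shift == log2FC``.
    """
    config = config or CohortConfig()
    metabolite_effects = metabolite_effects or default_metabolite_effects()
    cytokine_effects = cytokine_effects or default_cytokine_effects()

    order = ["M1_cytokines", "M2_pc_diacyl_short", "M3_short_polyunsaturated",
             "M4_long_lipids", "M5_small_molecules", "M6_pc_acylalkyl_lyso_short"]
    shifts = {name: config.metabolite_shift for name in order}
    shifts["M1_cytokines"] = config.cytokine_shift
    noise = {name: config.metabolite_noise_scale for name in order}
    noise["M1_cytokines"] = config.cytokine_noise_scale

    modules = {name: LatentModuleSpec(name, shift=shifts[name]) for name in order}
    for eff in cytokine_effects:
        _add_member(modules["M1_cytokines"], eff, noise["M1_cytokines"])
    for eff in metabolite_effects:
        name = _lipid_module_rule(eff.feature_id) or "M5_small_molecules"
        _add_member(modules[name], eff, noise[name])
    return [modules[name] for name in order]


def _add_member(module: LatentModuleSpec, eff: PlantedEffect,
                noise_scale: float) -> None:
    sign = 1 if eff.log2fc >= 0 else -1
    module.members[eff.feature_id] = ModuleMember(
        sign=sign, loading=abs(eff.log2fc) / module.shift,
        noise_sd=noise_scale * abs(eff.log2fc))


def _background_module_name(feature_id: str, feature_class: str) -> str | None:
    """Default module a non-planted feature is chemically akin to.

    Real serum panels are correlated within chemical classes whether or
    not a compound responds to disease; non-planted features therefore
    carry a weak loading on the factor of the module their chemistry
    matches (glycerophospholipids by the carbon/double-bond rules, other
    small molecules to the small-molecule module, cytokines to the
    cytokine module).  The hexose sum stays independent.
    """
    if feature_class == "cytokine":
        return "M1_cytokines"
    if feature_class == "hexose":
        return None
    if feature_class == "glycerophospholipid":
        return _lipid_module_rule(feature_id)
    return "M5_small_molecules"


def _check_disjoint(modules: list[LatentModuleSpec]) -> None:
    seen: dict[str, str] = {}
    for mod in modules:
        for fid in mod.members:
            if fid in seen:
                raise ValueError(
                    f"feature {fid!r} belongs to both {seen[fid]} and {mod.name}")
            seen[fid] = mod.name


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n_genes)]


def _module_factors(design: CohortDesign, modules: list[LatentModuleSpec],
                    latents: np.ndarray | None, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Module factors, shape (n_modules, n_samples).

    Returns ``(factors, within)`` where ``within`` is the group-centered
    within-group component and ``factors = within + shift * case``.  The
    within-group component is centered per group so that the factor's
    realized group-mean difference equals the shift exactly; planted fold
    changes of module members are then exact, not confounded by factor
    sampling noise shared across a whole module.
    """
    if latents is None:
        latents = rng.standard_normal((len(modules), design.n_samples))
    latents = np.asarray(latents, float)
    if latents.shape != (len(modules), design.n_samples):
        raise ValueError("latents must have shape (n_modules, n_samples)")
    case = design.case_indicator()
    u = latents.copy()
    for mask in (case == 1.0, case == 0.0):
        u[:, mask] -= u[:, mask].mean(axis=1, keepdims=True)
    shifts = np.array([m.shift for m in modules])
    return u + shifts[:, None] * case[None, :], u


def generate_gene_matrix(design: CohortDesign, n_genes: int,
                         planted: list[PlantedEffect] | None = None,
                         variance_prior: tuple[float, float] = (4.0, 0.05),
                         baseline_range: tuple[float, float] = (6.0, 14.0),
                         modules: list[LatentModuleSpec] | None = None,
                         latents: np.ndarray | None = None,
                         rng: np.random.Generator | None = None) -> OmicsMatrix:
    """Simulate a gene intensity matrix (n_genes x n_samples).

    Per-gene residual variances follow a scaled-inverse-chi-square prior
    with ``variance_prior = (d0, s0^2)``; planted effects shift case
    samples by the stated log2FC; genes listed as coupled in ``modules``
    are driven by the module factor instead (their group effect is
    ``kappa * shift``).  Values are returned on the intensity scale.
    """
    d0, s0sq = variance_prior
    if d0 <= 0 or s0sq <= 0:
        raise ValueError("variance prior requires d0 > 0 and s0sq > 0")
    planted = planted or []
    if n_genes < len(planted):
        raise ValueError("n_genes must be >= number of planted effects")
    rng = rng or np.random.default_rng(design.seed)
    ids = gene_ids(n_genes)
    known = set(ids)
    for eff in planted:
        if eff.feature_id not in known:
            raise ValueError(f"planted gene not in catalog: {eff.feature_id!r}")

    n = design.n_samples
    baseline = rng.uniform(*baseline_range, n_genes)
    sigma2 = d0 * s0sq / rng.chisquare(d0, n_genes)
    log2 = baseline[:, None] + rng.standard_normal((n_genes, n)) * np.sqrt(sigma2)[:, None]

    coupled: dict[str, tuple[int, float]] = {}
    if modules:
        factors, _ = _module_factors(design, modules, latents, rng)
        for mi, mod in enumerate(modules):
            for gid, kappa in mod.coupled.items():
                if gid not in known:
                    raise ValueError(f"coupled gene not in catalog: {gid!r}")
                coupled[gid] = (mi, kappa)

    case = design.case_indicator()
    index = pd.Index(ids)
    for eff in planted:
        if eff.feature_id in coupled:
            continue  # realized through the module factor below
        log2[index.get_loc(eff.feature_id)] += eff.log2fc * case
    for gid, (mi, kappa) in coupled.items():
        log2[index.get_loc(gid)] += kappa * factors[mi]

    values = pd.DataFrame(2.0 ** log2, index=index, columns=design.sample_ids())
    return OmicsMatrix(values, design.groups(), omic="gene")


def generate_serum_panel(design: CohortDesign,
                         catalog: pd.DataFrame | None = None,
                         modules: list[LatentModuleSpec] | None = None,
                         planted: list[PlantedEffect] | None = None,
                         latents: np.ndarray | None = None,
                         rng: np.random.Generator | None = None,
                         background_coupling: tuple[float, float] | None = (0.03, 0.09)
                         ) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Simulate the serum metabolite (uM) and cytokine (pg/ml) matrices.

    Module members are generated as
    ``baseline + sign * loading * factor + noise``; planted effects for
    features outside any module are applied as fixed case shifts (planted
    effects of module members are already realized by the factor and are
    ignored here).  Non-planted features additionally receive a weak
    random loading (magnitude drawn from ``background_coupling``) on the
    factor of the module their chemical class matches, emulating the
    within-class correlation of real serum panels; pass ``None`` to
    disable.  Returns ``(metabolites, cytokines)``.
    """
    if catalog is None:
        catalog = pd.concat(
            [default_metabolite_catalog(), default_cytokine_catalog()],
            ignore_index=True)
    modules = modules or []
    planted = planted or []
    _check_disjoint(modules)
    rng = rng or np.random.default_rng(design.seed)

    known = set(catalog["id"])
    member_of: dict[str, tuple[int, ModuleMember]] = {}
    for mi, mod in enumerate(modules):
        for fid, mem in mod.members.items():
            if fid not in known:
                raise ValueError(f"module member not in catalog: {fid!r}")
            member_of[fid] = (mi, mem)
    for eff in planted:
        if eff.feature_id not in known:
            raise ValueError(f"planted feature not in catalog: {eff.feature_id!r}")
    fixed = {e.feature_id: e.log2fc for e in planted
             if e.feature_id not in member_of}

    if modules:
        factors, within = _module_factors(design, modules, latents, rng)
    else:
        factors = within = np.zeros((0, design.n_samples))
    case = design.case_indicator()
    n = design.n_samples

    module_index = {mod.name: mi for mi, mod in enumerate(modules)}
    log2 = np.empty((len(catalog), n))
    for i, row in enumerate(catalog.itertuples(index=False)):
        fid = row.id
        if fid in member_of:
            mi, mem = member_of[fid]
            x = (row.baseline_log2 + mem.sign * mem.loading * factors[mi]
                 + rng.standard_normal(n) * mem.noise_sd)
        else:
            x = row.baseline_log2 + rng.standard_normal(n) * row.sd_log2
            if background_coupling is not None and modules:
                # weak loading on the *within-group* component only: the
                # feature stays a true null for the group contrast but
                # co-varies with its chemical class across patients
                home = _background_module_name(fid, row.feature_class)
                if home in module_index:
                    lam = rng.uniform(*background_coupling)
                    sign = rng.choice([-1.0, 1.0])
                    x = x + sign * lam * within[module_index[home]]
            if fid in fixed:
                x = x + fixed[fid] * case
        log2[i] = x

    values = pd.DataFrame(2.0 ** log2, index=pd.Index(catalog["id"]),
                          columns=design.sample_ids())
    groups = design.groups()
    is_cyto = (catalog["omic"] == "cytokine").values
    metab = OmicsMatrix(values.loc[~is_cyto], groups, omic="metabolite")
    cyto = OmicsMatrix(values.loc[is_cyto], groups, omic="cytokine")
    return metab, cyto


def censor_below_lod(matrix: OmicsMatrix,
                     lod: float | pd.Series,
                     seed: int | None = None) -> OmicsMatrix:
    """Replace values below the limit of detection with NaN.

    The censoring pattern is a deterministic function of the matrix and
    the per-feature (or scalar) threshold; ``seed`` is accepted for API
    symmetry with the other generators and unused.
    """
    if np.ndim(lod) == 0:
        lod = pd.Series(float(lod), index=matrix.values.index)
    else:
        lod = pd.Series(lod).reindex(matrix.values.index)
    if not np.isfinite(lod).all() or (lod < 0).any():
        raise ValueError("lod must be finite and non-negative")
    vals = matrix.values.copy()
    mask = vals.lt(lod, axis=0)
    vals[mask] = np.nan
    return matrix.with_values(vals)


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    genes: OmicsMatrix
    metabolites: OmicsMatrix
    cytokines: OmicsMatrix
    groups: pd.Series
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_tsv(outdir / "genes.tsv")
        self.metabolites.to_tsv(outdir / "metabolites.tsv")
        self.cytokines.to_tsv(outdir / "cytokines.tsv")
        write_groups(self.groups, outdir / "samples.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def default_gene_effects(config: CohortConfig,
                         rng: np.random.Generator) -> list[PlantedEffect]:
    ids = gene_ids(config.n_genes)
    chosen = rng.choice(config.n_genes, size=config.n_gene_effects, replace=False)
    lo, hi = config.gene_effect_range
    mags = rng.uniform(lo, hi, config.n_gene_effects)
    signs = rng.choice([-1.0, 1.0], config.n_gene_effects)
    return [PlantedEffect(ids[i], float(m * s))
            for i, m, s in zip(chosen, mags, signs)]


def generate_full_cohort(config: CohortConfig | dict | None = None
                         ) -> SyntheticCohort:
    """Generate the full three-layer cohort plus ground truth.

    Deterministic for a fixed config: the same seed yields byte-identical
    written files.
    """
    if config is None:
        config = CohortConfig()
    elif isinstance(config, dict):
        config = CohortConfig.from_dict(config)
    design = config.design()
    rng = np.random.default_rng(config.seed)

    if config.null_cohort:
        gene_effects, met_effects, cyto_effects = [], [], []
        modules: list[LatentModuleSpec] = []
    else:
        gene_effects = default_gene_effects(config, rng)
        met_effects = default_metabolite_effects()
        cyto_effects = default_cytokine_effects()
        modules = default_modules(config, met_effects, cyto_effects)

    # couple a disjoint slice of planted genes to each module's factor
    n_coupled = config.n_coupled_per_module * len(modules)
    if n_coupled > len(gene_effects) and modules:
        raise ValueError("n_coupled_per_module * 6 exceeds planted gene count")
    if modules:
        pick = rng.choice(len(gene_effects), size=n_coupled, replace=False)
        for j, idx in enumerate(pick):
            mod = modules[j % len(modules)]
            eff = gene_effects[idx]
            mod.coupled[eff.feature_id] = eff.log2fc / mod.shift

    latents = rng.standard_normal((len(modules), design.n_samples))

    genes = generate_gene_matrix(
        design, config.n_genes, gene_effects, config.variance_prior,
        config.gene_baseline_range, modules=modules, latents=latents, rng=rng)
    metab, cyto = generate_serum_panel(
        design, None, modules, met_effects + cyto_effects,
        latents=latents, rng=rng,
        background_coupling=config.background_coupling_range)

    truth = {
        "config": config.to_dict(),
        "planted_genes": {e.feature_id: e.log2fc for e in gene_effects},
        "planted_metabolites": {e.feature_id: e.log2fc for e in met_effects},
        "planted_cytokines": {e.feature_id: round(e.log2fc, 6)
                              for e in cyto_effects},
        "modules": {
            m.name: {
                "shift": m.shift,
                "members": {fid: {"sign": mem.sign,
                                  "loading": round(mem.loading, 6),
                                  "noise_sd": round(mem.noise_sd, 6)}
                            for fid, mem in m.members.items()},
                "coupled": {g: round(k, 6) for g, k in m.coupled.items()},
            } for m in modules
        },
    }
    return SyntheticCohort(genes, metab, cyto, design.groups(), truth)


def make_gene_sets(truth: dict, n_random: int = 30,
                   size_range: tuple[int, int] = (10, 40),
                   seed: int = 0) -> dict[str, list[str]]:
    """Synthetic gene-set collection for end-to-end enrichment runs.

    One set per latent module containing exactly its coupled genes, plus
    ``n_random`` background sets sampled uniformly from the gene universe.
    """
    rng = np.random.default_rng(seed)
    n_genes = truth["config"]["n_genes"]
    ids = gene_ids(n_genes)
    sets: dict[str, list[str]] = {}
    for name, mod in truth["modules"].items():
        if mod["coupled"]:
            sets[f"COUPLED_{name}"] = sorted(mod["coupled"])
    lo, hi = size_range
    for j in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        sets[f"RANDOM_{j + 1:03d}"] = sorted(ids[i] for i in members)
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")
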