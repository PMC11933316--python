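"""Synthetic pooled-screen generator with ground truth.

The generator emulates a genome-wide knockout screen of the kind run with
a Brunello-style library (4 guides per gene plus non-targeting controls,
two replicates, vehicle vs drug arms sampled every other day out to Day
10) and a small tiling library scanning the coding region of one gene.

Abundance model
---------------
Each sgRNA *i* targeting gene *g* starts at library fraction
:math:`p_i(0)` (log-normal across the library, controlling representation
skew) and evolves by exponential selection

.. math:: p_i(t) \\propto p_i(0)\\,\\exp\\big[(g_g + \\mathbf{1}[c=\\mathrm{drug}]\\,e_g)\\,w_i\\,t/\\tau\\big],

renormalized to sum to one, where :math:`g_g` is the condition-shared
log-fitness of the knockout, :math:`e_g` its extra treatment interaction,
:math:`w_i \\in [0,1]` a per-guide cutting efficiency, and :math:`\\tau`
the time constant converting effect size to per-day log-growth.  Reads
are drawn negative-binomially around :math:`\\mu_{i}= \\mathrm{depth}\\cdot
p_i(t)` with ``Var = mu + alpha*mu**2`` via a Gamma–Poisson mixture (valid
for non-integer :math:`1/\\alpha`).  The Day-0 baseline is drawn once per
replicate and shared between arms.

Random streams are split hierarchically per (replicate, condition, day)
so draws are reproducible independent of sampling order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ConsistencyError
from .library import CountMatrix, NTC_GENE, SgRNALibrary, sample_name

__all__ = [
    "SimConfig", "SimTruth", "DomainSpec", "KDM1A_DOMAIN_SPEC",
    "make_library", "draw_effects", "draw_tiling_effects",
    "simulate_screen", "make_tiling_library", "expected_fractions",
]


@dataclass
class SimConfig:
    """Screen-simulation settings.

    Defaults mirror the study design the analysis targets: two replicates,
    DMSO vs DAC arms, samples at Days 0–10 every other day, and a
    sequencing depth giving a few-hundred-fold guide coverage.
    """

    n_genes: int = 1000
    sgrnas_per_gene: int = 4
    n_ntc: int = 100
    timepoints_days: tuple[int, ...] = (0, 2, 4, 6, 8, 10)
    n_replicates: int = 2
    depth_per_sample: int = 1_000_000
    dispersion_sim: float = 0.05
    skew_sigma: float = 0.5
    tau_days: float = 2.0
    seed: int = 0
    conditions: tuple[str, str] = ("DMSO", "DAC")

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.timepoints_days)
        if len(days) < 1 or days[0] != 0:
            raise ConfigError("timepoints_days must start at 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError("timepoints_days must be strictly increasing")
        self.timepoints_days = days
        self.conditions = tuple(self.conditions)
        if len(self.conditions) != 2:
            raise ConfigError("exactly two conditions (vehicle, drug) expected")
        if self.dispersion_sim < 0:
            raise ConfigError("dispersion_sim must be >= 0")
        if self.tau_days <= 0:
            raise ConfigError("tau_days must be positive")
        for name in ("n_genes", "sgrnas_per_gene", "n_replicates", "depth_per_sample"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_ntc < 0:
            raise ConfigError("n_ntc must be non-negative")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["timepoints_days"] = list(d["timepoints_days"])
        d["conditions"] = list(d["conditions"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: not a mapping")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class SimTruth:
    """Ground truth emitted by the effect-drawing step.

    ``effects``: per selection unit (gene, or domain in tiling screens) —
    ``baseline_effect`` (g) and ``treatment_effect`` (e), both log-fitness
    per tau days.  ``guides``: per sgRNA — its unit, cutting efficiency
    ``w`` in [0, 1], initial library fraction ``p0`` (summing to 1), and
    the resolved per-guide ``g``/``e``.
    """

    effects: pd.DataFrame
    guides: pd.DataFrame

    def __post_init__(self) -> None:
        tot = float(self.guides["p0"].sum())
        if abs(tot - 1.0) > 1e-9:
            raise ConsistencyError(f"initial fractions sum to {tot}, not 1")

    def to_tsv(self, effects_path, guides_path) -> None:
        eff = self.effects.rename_axis("gene")
        eff.to_csv(effects_path, sep="\t")
        g = self.guides.rename(columns={"w": "efficiency", "p0": "initial_fraction"})
        g.rename_axis("sgRNA").to_csv(guides_path, sep="\t")

    @classmethod
    def from_tsv(cls, effects_path, guides_path) -> "SimTruth":
        eff = pd.read_csv(effects_path, sep="\t", index_col="gene")
        g = pd.read_csv(guides_path, sep="\t", index_col="sgRNA")
        g = g.rename(columns={"efficiency": "w", "initial_fraction": "p0"})
        return cls(eff, g)


def make_library(n_genes: int, sgrnas_per_gene: int, n_ntc: int,
                 seed: int = 0) -> SgRNALibrary:
    """Construct a genome-wide-style library: ``n_genes`` genes with
    ``sgrnas_per_gene`` guides each plus ``n_ntc`` non-targeting controls."""
    if n_genes <= 0 or sgrnas_per_gene <= 0:
        raise ConfigError("n_genes and sgrnas_per_gene must be positive")
    if n_ntc < 0:
        raise ConfigError("n_ntc must be non-negative")
    gw = max(4, len(str(n_genes)))
    rows = []
    for gi in range(1, n_genes + 1):
        gene = f"G{gi:0{gw}d}"
        for j in range(1, sgrnas_per_gene + 1):
            rows.append((f"{gene}_sg{j}", gene, "targeting"))
    for j in range(1, n_ntc + 1):
        rows.append((f"NTC_sg{j:03d}", NTC_GENE, "nontargeting"))
    table = pd.DataFrame(rows, columns=["sgRNA", "gene", "class"])
    return SgRNALibrary(table)


def _draw_p0(n: int, skew_sigma: float, rng: np.random.Generator) -> np.ndarray:
    raw = np.exp(rng.normal(0.0, skew_sigma, size=n)) if skew_sigma > 0 else np.ones(n)
    return raw / raw.sum()


def draw_effects(library: SgRNALibrary, frac_resist: float, frac_sens: float,
                 effect_size: float, seed: int = 0, *,
                 baseline_sd: float = 0.1, efficiency_shape: tuple[float, float] = (5.0, 1.0),
                 skew_sigma: float = 0.5) -> SimTruth:
    """Plant condition-specific effects on random genes.

    ``floor(frac_resist * n_genes)`` genes get treatment effect
    ``+effect_size`` (resistance hits), ``floor(frac_sens * n_genes)`` get
    ``-effect_size`` (sensitization hits); baseline effects are
    Normal(0, ``baseline_sd``) for every targeting gene.  Guide
    efficiencies are Beta(5, 1); controls get w = g = e = 0.
    """
    for name, v in (("frac_resist", frac_resist), ("frac_sens", frac_sens)):
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1]")
    if frac_resist + frac_sens > 1.0:
        raise ConfigError("frac_resist + frac_sens must be <= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))

    genes = library.genes
    n = len(genes)
    n_r = int(np.floor(frac_resist * n))
    n_s = int(np.floor(frac_sens * n))
    chosen = rng.choice(n, size=n_r + n_s, replace=False)
    e = np.zeros(n)
    e[chosen[:n_r]] = +effect_size
    e[chosen[n_r:]] = -effect_size
    g = rng.normal(0.0, baseline_sd, size=n)

    effects = pd.DataFrame({"baseline_effect": g, "treatment_effect": e}, index=genes)
    effects.index.name = "gene"
    # non-gene units (NTC, positive controls) carry zero effects by default
    other = sorted(set(library.table["gene"]) - set(genes))
    if other:
        zero = pd.DataFrame(0.0, index=other,
                            columns=["baseline_effect", "treatment_effect"])
        effects = pd.concat([effects, zero])

    guides = _resolve_guides(library, effects, rng,
                             efficiency_shape=efficiency_shape,
                             skew_sigma=skew_sigma)
    return SimTruth(effects=effects, guides=guides)


def draw_tiling_effects(library: SgRNALibrary, domain_effects: dict[str, float],
                        seed: int = 0, *, control_effect: float = 1.0,
                        baseline_sd: float = 0.0,
                        efficiency_shape: tuple[float, float] = (5.0, 1.0),
                        skew_sigma: float = 0.5) -> SimTruth:
    """Ground truth for a tiling screen: effects are assigned per domain.

    ``domain_effects`` maps domain label → treatment effect e; domains not
    listed get 0.  Positive-control guides get ``control_effect``
    (knockout of the drug-activating kinase confers resistance, so the
    default is enrichment under treatment).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    domains = [d for d in library.table["domain"].dropna().unique()]
    unknown = set(domain_effects) - set(domains)
    if unknown:
        raise ConfigError(f"domain_effects names unknown domains {sorted(unknown)}")
    units = list(domains) + sorted(
        set(library.table.loc[library.table["class"] == "control", "gene"])
    ) + [NTC_GENE]
    effects = pd.DataFrame(0.0, index=units,
                           columns=["baseline_effect", "treatment_effect"])
    effects.index.name = "gene"
    for d in domains:
        effects.loc[d, "treatment_effect"] = float(domain_effects.get(d, 0.0))
    for cg in library.table.loc[library.table["class"] == "control", "gene"].unique():
        effects.loc[cg, "treatment_effect"] = control_effect
    if baseline_sd > 0:
        effects.loc[domains, "baseline_effect"] = rng.normal(0, baseline_sd, len(domains))

    guides = _resolve_guides(library, effects, rng, unit_by_domain=True,
                             efficiency_shape=efficiency_shape,
                             skew_sigma=skew_sigma)
    return SimTruth(effects=effects, guides=guides)


def _resolve_guides(library: SgRNALibrary, effects: pd.DataFrame,
                    rng: np.random.Generator, *, unit_by_domain: bool = False,
                    efficiency_shape=(5.0, 1.0), skew_sigma: float = 0.5) -> pd.DataFrame:
    tab = library.table
    if unit_by_domain:
        unit = tab["domain"].where(tab["domain"].notna(), tab["gene"])
    else:
        unit = tab["gene"]
    unit = unit.astype(str)
    is_target = (tab["class"] != "nontargeting").to_numpy()
    a, b = efficiency_shape
    w = np.where(is_target, rng.beta(a, b, size=len(tab)), 0.0)
    p0 = _draw_p0(len(tab), skew_sigma, rng)
    g = effects["baseline_effect"].reindex(unit).to_numpy()
    e = effects["treatment_effect"].reindex(unit).to_numpy()
    guides = pd.DataFrame(
        {"unit": unit.to_numpy(), "w": w, "p0": p0, "g": g, "e": e},
        index=pd.Index(tab["sgRNA"], name="sgRNA"),
    )
    # non-targeting guides are inert by definition
    ntc = (tab["class"] == "nontargeting").to_numpy()
    guides.loc[ntc, ["w", "g", "e"]] = 0.0
    return guides


def expected_fractions(truth: SimTruth, day: float, treated: bool,
                       tau_days: float, renormalize: bool = True) -> pd.Series:
    """Expected relative abundance of every sgRNA at ``day`` under the
    exponential-selection model (the simulator's own mean function)."""
    g = truth.guides
    rate = (g["g"] + (g["e"] if treated else 0.0)) * g["w"] / tau_days
    p = g["p0"] * np.exp(rate * day)
    return p / p.sum() if renormalize else p


def _nb_draw(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2, via Gamma–Poisson."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


_COND_CODE = {"BASE": 0}


def _stream(seed: int, replicate: int, condition: str, day: int) -> np.random.Generator:
    code = _COND_CODE.get(condition)
    if code is None:
        code = 1000 + sum(ord(c) * (31 ** i) for i, c in enumerate(condition)) % 100_000
    ss = np.random.SeedSequence([int(seed), int(replicate), int(code), int(day)])
    return np.random.default_rng(ss)


def simulate_screen(library: SgRNALibrary, truth: SimTruth,
                    config: SimConfig) -> CountMatrix:
    """Draw a full count matrix for every (replicate, condition, day).

    Day 0 is a single shared baseline sample per replicate (condition
    ``BASE``); each later day has one sample per condition per replicate.
    """
    missing = set(library.sgrna_ids) - set(truth.guides.index)
    if missing:
        raise ConsistencyError(
            f"truth table missing sgRNA {sorted(missing)[0]!r} "
            f"({len(missing)} missing total)"
        )
    guides = truth.guides.reindex(library.sgrna_ids)
    if config.depth_per_sample < 10 * len(library):
        warnings.warn(
            "depth_per_sample below 10x library size; counts will be sparse"
        )

    cols: dict[str, np.ndarray] = {}
    meta: list[tuple[str, str, int, int]] = []
    p0 = guides["p0"].to_numpy()
    for r in range(1, config.n_replicates + 1):
        rng = _stream(config.seed, r, "BASE", 0)
        name = sample_name(r, "BASE", 0)
        cols[name] = _nb_draw(config.depth_per_sample * p0,
                              config.dispersion_sim, rng)
        meta.append((name, "BASE", 0, r))
        for day in config.timepoints_days[1:]:
            for cond in config.conditions:
                treated = cond == config.conditions[1]
                rate = (guides["g"] + (guides["e"] if treated else 0.0)) \
                    * guides["w"] / config.tau_days
                p = p0 * np.exp(rate.to_numpy() * day)
                p = p / p.sum()
                rng = _stream(config.seed, r, cond, day)
                name = sample_name(r, cond, day)
                cols[name] = _nb_draw(config.depth_per_sample * p,
                                      config.dispersion_sim, rng)
                meta.append((name, cond, day, r))

    counts = pd.DataFrame(cols, index=library.sgrna_ids).astype(np.int64)
    samples = pd.DataFrame(meta, columns=["sample", "condition", "day", "replicate"]
                           ).set_index("sample")
    return CountMatrix(counts=counts, samples=samples, genes=library.gene_of())


# ---------------------------------------------------------------------------
# tiling libraries


@dataclass(frozen=True)
class DomainSpec:
    """A named protein-domain interval on the coding sequence (1-based,
    inclusive nucleotide positions) with the number of tiling guides in it."""
    name: str
    start: int
    end: int
    n_sgrnas: int


#: Default tiling design modelled on a demethylase-gene domain scan:
#: 58 coding-region guides split across the N-terminal flexible region
#: (NFR), the SWIRM domain, the two lobes of the amine-oxidase domain and
#: the Tower insertion.  Counts sum to 58.
KDM1A_DOMAIN_SPEC: tuple[DomainSpec, ...] = (
    DomainSpec("NFR", 1, 513, 12),
    DomainSpec("SWIRM", 514, 813, 7),
    DomainSpec("AOD_N", 814, 1251, 10),
    DomainSpec("Tower", 1252, 1569, 7),
    DomainSpec("AOD_C", 1570, 2559, 22),
)


def make_tiling_library(domain_spec=KDM1A_DOMAIN_SPEC, seed: int = 0, *,
                        gene: str = "KDM1A", n_ntc: int = 10,
                        controls: tuple[tuple[str, int], ...] = (("DCK", 2),),
                        total: int | None = None) -> SgRNALibrary:
    """Build a tiling library: domain-annotated guides at random coding
    positions, plus positive-control and non-targeting guides."""
    spec = [d if isinstance(d, DomainSpec) else DomainSpec(*d) for d in domain_spec]
    if not spec:
        raise ConfigError("domain_spec is empty")
    for d in spec:
        if d.n_sgrnas <= 0 or d.start < 1 or d.end < d.start:
            raise ConfigError(f"invalid domain spec {d}")
        if d.end - d.start + 1 < d.n_sgrnas:
            raise ConfigError(f"domain {d.name}: more guides than positions")
    if total is not None and sum(d.n_sgrnas for d in spec) != total:
        raise ConfigError(
            f"per-domain sgRNA counts sum to {sum(d.n_sgrnas for d in spec)}, "
            f"expected {total}"
        )
    ivals = sorted((d.start, d.end, d.name) for d in spec)
    for (s1, e1, n1), (s2, e2, n2) in zip(ivals, ivals[1:]):
        if s2 <= e1:
            warnings.warn(f"domain intervals {n1} and {n2} overlap")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    rows = []
    for d in spec:
        pos = np.sort(rng.choice(np.arange(d.start, d.end + 1),
                                 size=d.n_sgrnas, replace=False))
        for p in pos:
            rows.append((None, gene, "targeting", d.name, int(p)))
    rows.sort(key=lambda r: r[4])
    rows = [(f"{gene}_sg{j + 1:02d}",) + r[1:] for j, r in enumerate(rows)]
    for cg, n in controls:
        for j in range(1, n + 1):
            rows.append((f"{cg}_sg{j}", cg, "control", None, None))
    for j in range(1, n_ntc + 1):
        rows.append((f"NTC_sg{j:02d}", NTC_GENE, "nontargeting", None, None))
    table = pd.DataFrame(rows, columns=["sgRNA", "gene", "class", "domain", "cds_pos"])
    table["cds_pos"] = table["cds_pos"].astype("Int64")
    return SgRNALibrary(table)
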