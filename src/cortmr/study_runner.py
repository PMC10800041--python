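"""Multi-outcome study grid: enumerate the cortical outcome set, run the
full MR pipeline per cell, and apply family-wise Bonferroni control.

The default grid follows a 34-parcel cortical atlas: each region
contributes surface area (SA) and thickness (TH), each analysed with (w)
and without (nw) whole-brain weighting, plus one global cell per
measure — 34 x 2 x 2 + 2 = 138 analyses.  Per cell the pipeline is
instrument harmonization -> IVW (primary) plus supplementary estimators
-> sensitivity battery -> survive/fail verdict -> significance tier
("meaningful" below the Bonferroni threshold alpha/138, "nominal" below
0.05).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gwas_io import LDTable
from .instruments import SelectionConfig, build_instruments
from .estimators import MRResult, ivw, run_all
from .sensitivity import SensitivityReport, run_sensitivity

#: The 34 cortical parcel names of the Desikan-Killiany atlas.
DESIKAN_KILLIANY = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

MEASURES = ("SA", "TH")
WEIGHTINGS = ("w", "nw")


@dataclass(frozen=True, order=True)
class RegionSpec:
    """One grid cell: a cortical region, measure, and weighting scheme.

    Global cells use ``region='global'`` and carry no weighting label
    (one cell per measure).
    """
    region: str
    measure: str
    weighting: str | None = None

    @property
    def label(self) -> str:
        if self.weighting is None:
            return f"{self.region}__{self.measure}"
        return f"{self.region}__{self.measure}__{self.weighting}"

    @classmethod
    def from_label(cls, label: str) -> "RegionSpec":
        parts = label.split("__")
        if len(parts) == 2:
            return cls(parts[0], parts[1], None)
        if len(parts) == 3:
            return cls(parts[0], parts[1], parts[2])
        raise ConfigError(f"cannot parse cell label: {label}")


@dataclass
class StudyGrid:
    cells: tuple[RegionSpec, ...]
    alpha_family: float = 0.05

    def __len__(self) -> int:
        return len(self.cells)


def build_grid(regions=DESIKAN_KILLIANY, include_global: bool = True,
               alpha_family: float = 0.05) -> StudyGrid:
    """Enumerate the outcome grid in deterministic order.

    Regions alphabetical; per region SA before TH and w before nw;
    global cells (one per measure) last.
    """
    regions = list(regions)
    if len(set(regions)) != len(regions):
        raise ConfigError("duplicate region names in atlas list")
    cells = [RegionSpec(r, m, wt)
             for r in sorted(regions) for m in MEASURES for wt in WEIGHTINGS]
    if include_global:
        cells += [RegionSpec("global", m, None) for m in MEASURES]
    return StudyGrid(tuple(cells), alpha_family)


def bonferroni_threshold(alpha_family: float, n_tests: int):
    """Family-wise threshold alpha/n and its one-significant-figure display."""
    if n_tests < 1:
        raise ConfigError("n_tests must be >= 1")
    exact = alpha_family / n_tests
    display = float(f"{exact:.0e}")
    return exact, display


@dataclass(frozen=True)
class StudyConfig:
    """Estimation and sensitivity settings shared across grid cells."""
    alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    methods: tuple[str, ...] = ("ivw_re", "egger", "weighted_median",
                                "simple_mode", "weighted_mode")
    confounder_traits: tuple[str, ...] = (
        "body mass index", "obesity", "smoking", "drinking",
        "neuropsychiatric disease", "hypertension", "hyperlipemia")


@dataclass
class CellResult:
    spec: RegionSpec
    status: str                      # "ok" | "not_estimable"
    ivw: MRResult | None = None
    methods: dict = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    tier: str = "ns"                 # "meaningful" | "nominal" | "ns"
    n_snp: int = 0


@dataclass
class StudyResult:
    grid: StudyGrid
    cells: dict                      # RegionSpec -> CellResult
    bonferroni: float
    bonferroni_display: float
    attrition: dict

    @property
    def nominal(self) -> list[RegionSpec]:
        return [s for s, c in self.cells.items()
                if c.status == "ok" and c.ivw.pval < 0.05]

    @property
    def meaningful(self) -> list[RegionSpec]:
        return [s for s, c in self.cells.items() if c.tier == "meaningful"]

    @property
    def survivors(self) -> list[RegionSpec]:
        return [s for s in self.nominal
                if self.cells[s].sensitivity is not None
                and self.cells[s].sensitivity.verdict == "survive"]

    def results_frame(self) -> pd.DataFrame:
        """Long results table, one row per cell, deterministic order."""
        rows = []
        for spec in self.grid.cells:
            c = self.cells[spec]
            if c.status != "ok":
                rows.append({"cell": spec.label, "region": spec.region,
                             "measure": spec.measure,
                             "weighting": spec.weighting or "",
                             "status": c.status, "n_snp": 0,
                             "beta": np.nan, "se": np.nan, "pval": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "tier": "ns", "verdict": ""})
                continue
            sens = c.sensitivity
            rows.append({
                "cell": spec.label, "region": spec.region,
                "measure": spec.measure, "weighting": spec.weighting or "",
                "status": "ok", "n_snp": c.n_snp,
                "beta": c.ivw.beta, "se": c.ivw.se, "pval": c.ivw.pval,
                "ci_low": c.ivw.ci_low, "ci_high": c.ivw.ci_high,
                "tier": c.tier,
                "verdict": sens.verdict if sens is not None else "",
            })
        return pd.DataFrame(rows)


def run_study(exposure: pd.DataFrame, outcomes: dict, ld: LDTable,
              selection: SelectionConfig = SelectionConfig(),
              study: StudyConfig = StudyConfig(),
              grid: StudyGrid | None = None,
              n_exposure: int | None = None, n_outcome: int | None = None,
              annotation: dict | None = None, seed: int = 0) -> StudyResult:
    """Run the full pipeline over every grid cell.

    Instruments are extracted and clumped once from the shared exposure
    GWAS; matching, harmonization and strength filtering are per cell
    (each cell has its own outcome table).  A cell whose instrument set
    comes out empty, or with too few instruments for IVW, is recorded as
    ``not_estimable`` and never aborts the study.
    """
    if grid is None:
        keys = list(outcomes)
        cells = tuple(k if isinstance(k, RegionSpec) else RegionSpec.from_label(str(k))
                      for k in keys)
        grid = StudyGrid(cells)
    if n_exposure is None:
        n_exposure = int(exposure["n"].iloc[0])
    outcome_of = {}
    for k, v in outcomes.items():
        spec = k if isinstance(k, RegionSpec) else RegionSpec.from_label(str(k))
        outcome_of[spec] = v

    n_tests = len(grid.cells)
    bonf, bonf_disp = bonferroni_threshold(grid.alpha_family, n_tests)

    cells: dict[RegionSpec, CellResult] = {}
    attrition: dict[str, dict] = {}
    for i, spec in enumerate(grid.cells):
        out_tab = outcome_of.get(spec)
        if out_tab is None or len(out_tab) == 0:
            cells[spec] = CellResult(spec, "not_estimable")
            continue
        sel = build_instruments(exposure, out_tab, ld, selection, n_exposure)
        attrition[spec.label] = sel.attrition
        if sel.empty or len(sel.table) < 2:
            cells[spec] = CellResult(spec, "not_estimable")
            continue
        n_out = n_outcome if n_outcome is not None \
            else int(out_tab["n"].iloc[0])
        cell_seed = int(np.random.SeedSequence(
            [seed & 0x7FFFFFFF, i]).generate_state(1)[0] & 0x7FFFFFFF)
        methods = run_all(sel.table, n_boot=study.n_boot, seed=cell_seed,
                          methods=study.methods)
        primary = methods.get("ivw_re") or ivw(sel.table)
        sens = run_sensitivity(
            sel.table, n_exposure, n_out, mr_result=primary,
            annotation=annotation, confounder_traits=study.confounder_traits,
            alpha=study.alpha, n_sim=study.n_sim, seed=cell_seed)
        tier = "meaningful" if primary.pval < bonf else \
            ("nominal" if primary.pval < 0.05 else "ns")
        cells[spec] = CellResult(spec, "ok", primary, methods, sens, tier,
                                 len(sel.table))
    return StudyResult(grid, cells, bonf, bonf_disp, attrition)
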