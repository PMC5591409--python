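"""End-to-end orchestration: simulate or ingest a cohort, bin, fit pairwise
OPLS-DA models, validate (permutation + CV-ANOVA), pick and quantify
biomarkers, and write a run report.

Every stage writes its intermediate as a tab-separated file in the output
directory, and the report is regenerated purely from those intermediates, so
a run is re-entrant and fully determined by (config, seed). Report bodies
carry no timestamps; rerunning an identical config reproduces them byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .biomarkers import (
    compute_s_plot,
    compute_vip,
    map_bins_to_metabolites,
    quantify_cohort,
    select_discriminants,
    univariate_table,
)
from .opls import OPLSDA
from .pca import PCA
from .preprocess import (
    assemble_bin_matrix,
    bin_spectrum,
    build_bin_grid,
    normalize_percent,
    read_manifest,
    read_spectrum,
    write_manifest,
    write_spectrum,
)
from .scale import pareto_scale
from .simulate import (
    AcquisitionParams,
    CohortDesign,
    GROUPS,
    build_default_library,
    load_library,
    simulate_cohort,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "generate_report"]

log = logging.getLogger("nmrmetab")

DEFAULT_COMPARISONS = [("C", "NR"), ("C", "R"), ("R", "NR")]


@dataclass
class PipelineConfig:
    """Single structured configuration for a full run.

    Defaults mirror the standard analysis settings: 0.04-ppm buckets over
    0.6-8.6 ppm with the residual-water (4.64-5.2) and noise (5.28-6.6)
    regions excluded, 7-fold cross-validation, 500 label permutations, one
    predictive + one orthogonal component, alpha = 0.05.
    """

    mode: str = "simulate"                      # simulate | manifest
    manifest: str | None = None
    design: tuple[int, int, int] = (35, 18, 17)  # C, R, NR group sizes
    seed: int = 0
    library: str | None = None                  # path; None = packaged default
    noise_sd: float | None = None
    bin_lo: float = 0.6
    bin_hi: float = 8.6
    bin_width: float = 0.04
    exclusions: list[tuple[float, float]] = field(
        default_factory=lambda: [(4.64, 5.2), (5.28, 6.6)]
    )
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_COMPARISONS)
    )
    n_orth: int = 1
    folds: int = 7
    n_perm: int = 500
    perm_mode: str = "plsda"
    pcorr_min: float = 0.5
    vip_min: float = 1.0
    alpha: float = 0.05
    out_dir: str = "nmrmetab_run"

    def validate(self) -> None:
        if self.mode not in ("simulate", "manifest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "manifest":
            if not self.manifest or not Path(self.manifest).exists():
                raise ValueError("manifest mode requires an existing manifest file")
        declared = set(GROUPS)
        for g1, g2 in self.comparisons:
            if g1 not in declared or g2 not in declared:
                raise ValueError(f"comparison {g1}:{g2} references unknown group")
        if self.library is not None and not Path(self.library).exists():
            raise ValueError(f"library file {self.library} not found")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("exclusions", "comparisons"):
                val = [tuple(v) for v in val]
            elif key == "design":
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg

    def digest(self) -> str:
        # out_dir only says where results land, not what was computed
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config: PipelineConfig
    model_table: "pd.DataFrame"      # Table of per-comparison model statistics
    univariate: "pd.DataFrame"
    discriminants: dict[str, "pd.DataFrame"] = field(default_factory=dict)
    out_dir: Path = Path(".")

    def render(self) -> str:
        from . import __version__ as version

        lines = [
            "# Cohort chemometrics run report",
            "",
            f"- package version: {version}",
            f"- config digest: {self.config.digest()}",
            f"- seed: {self.config.seed}",
            "",
            "## Model summary (per comparison)",
            "",
            self.model_table.to_string(index=False),
            "",
            "## Discriminant buckets",
            "",
        ]
        for tag, disc in self.discriminants.items():
            if disc.empty:
                lines.append(f"- {tag}: no bucket passed the selection thresholds")
            else:
                named = disc.loc[disc["metabolites"] != "unassigned", "metabolites"]
                mets = sorted(set(";".join(named).split(";"))) if len(named) else []
                lines.append(
                    f"- {tag}: {len(disc)} bucket(s) selected"
                    + (f" -> {', '.join(mets)}" if mets else "")
                )
        lines += ["", "## Univariate confirmation (quantified metabolites)", ""]
        if self.univariate.empty:
            lines.append("No metabolites were quantified.")
        else:
            lines.append(self.univariate.to_string(index=False))
        lines.append("")
        return "\n".join(lines)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception:
                log.exception("stage %s: failed", name)
                raise
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


@_stage("ingest")
def _load_cohort(cfg: PipelineConfig, out: Path):
    library = load_library(cfg.library) if cfg.library else build_default_library()
    if cfg.mode == "simulate":
        acq_kwargs = {}
        if cfg.noise_sd is not None:
            acq_kwargs["noise_sd"] = cfg.noise_sd
        acq = AcquisitionParams(**acq_kwargs)
        design = CohortDesign(*cfg.design, seed=cfg.seed)
        spectra, truth = simulate_cohort(design, library, acq)
        spec_dir = out / "spectra"
        spec_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for s in spectra:
            p = spec_dir / f"{s.sample_id}.tsv"
            write_spectrum(s, p)
            manifest_rows.append((s.sample_id, s.group or "", str(p)))
        write_manifest(manifest_rows, out / "manifest.tsv")
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False,
                     float_format="%.10g")
    else:
        df = read_manifest(cfg.manifest)
        spectra = []
        for _, row in df.iterrows():
            s = read_spectrum(row["path"])
            s.sample_id, s.group = row["sample_id"], row["group"]
            spectra.append(s)
    return spectra, library


@_stage("bin")
def _bin_cohort(cfg: PipelineConfig, spectra, out: Path):
    grid = build_bin_grid(cfg.bin_lo, cfg.bin_hi, cfg.bin_width, cfg.exclusions)
    binned = [normalize_percent(bin_spectrum(s, grid)) for s in spectra]
    matrix = assemble_bin_matrix(binned, grid)
    matrix.to_tsv(out / "matrix.tsv")
    return matrix


@_stage("pca_screen")
def _pca_screen(cfg: PipelineConfig, matrix, out: Path):
    import pandas as pd

    x_scaled, _ = pareto_scale(matrix)
    n_comp = min(2, matrix.n_samples - 1, matrix.n_bins)
    res = PCA(x_scaled, n_comp=n_comp).fit()
    flags = res.outlier_flags(cfg.alpha)
    if flags.any():
        log.warning("PCA screen: %d potential outlier(s) flagged (report-only)",
                    int(flags.sum()))
    pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group": matrix.groups,
            "t1": res.scores[:, 0],
            "t2": res.scores[:, 1] if n_comp > 1 else 0.0,
            "hotelling_t2": res.hotelling_t2(),
            "outlier": flags,
        }
    ).to_csv(out / "pca_screen.tsv", sep="\t", index=False, float_format="%.6g")
    return res


@_stage("models")
def _fit_comparisons(cfg: PipelineConfig, matrix, library, out: Path):
    import pandas as pd

    rows = []
    for g1, g2 in cfg.comparisons:
        tag = f"{g1}_vs_{g2}"
        cmp_dir = out / tag
        cmp_dir.mkdir(exist_ok=True)
        sub = matrix.subset((g1, g2))
        model = OPLSDA(sub, classes=(g1, g2), n_orth=cfg.n_orth)
        res = model.fit(folds=cfg.folds)
        res.scores_frame().to_csv(cmp_dir / "scores.tsv", sep="\t", index=False,
                                  float_format="%.6g")

        perm = res.permutation_test(n_perm=cfg.n_perm, seed=cfg.seed,
                                    mode=cfg.perm_mode)
        perm.to_tsv(cmp_dir / "permutation.tsv")
        anova = res.cv_anova()

        splot = res.s_plot()
        vip = res.vip()
        splot.to_csv(cmp_dir / "splot.tsv", sep="\t", index=False,
                     float_format="%.6g")
        vip.to_csv(cmp_dir / "vip.tsv", sep="\t", index=False,
                   float_format="%.6g")
        disc = select_discriminants(splot, vip, cfg.pcorr_min, cfg.vip_min,
                                    classes=(g1, g2))
        mapped = map_bins_to_metabolites(disc, matrix.grid, library)
        disc.merge(mapped, on="bin").to_csv(
            cmp_dir / "discriminants.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        (cmp_dir / "model.txt").write_text(res.summary() + "\n")

        rows.append(
            {
                "comparison": f"{g1} vs {g2}",
                "components": res.component_spec,
                "R2Xcum": round(res.r2x_cum, 3),
                "R2Ycum": round(res.r2y_cum, 3),
                "Q2cum": round(res.q2_cum, 3),
                "p_cv_anova": float(f"{anova.p:.3g}"),
                "R2_intercept": round(perm.r2_intercept, 3),
                "Q2_intercept": round(perm.q2_intercept, 3),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "model_table.tsv", sep="\t", index=False)
    return table


@_stage("quantify")
def _quantify(cfg: PipelineConfig, spectra, library, out: Path):
    conc = quantify_cohort(spectra, library)
    conc.to_csv(out / "concentrations.tsv", sep="\t", index=False,
                float_format="%.6g")
    uni = univariate_table(conc, cfg.comparisons)
    uni.to_csv(out / "univariate.tsv", sep="\t", index=False,
               float_format="%.6g")
    return conc, uni


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis for every configured comparison.

    Stages: ingest/simulate -> bin -> PCA screen -> per-comparison OPLS-DA +
    permutation + CV-ANOVA + S-plot/VIP selection -> quantification ->
    univariate confirmation -> report. Idempotent for a fixed (config, seed).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra, library = _load_cohort(cfg, out)
    matrix = _bin_cohort(cfg, spectra, out)
    _pca_screen(cfg, matrix, out)
    _fit_comparisons(cfg, matrix, library, out)
    _quantify(cfg, spectra, library, out)
    # the report is always regenerated from the serialized intermediates so
    # that rebuilding it later reproduces the original byte for byte
    return generate_report(out, cfg)


def generate_report(out_dir: str | Path, cfg: PipelineConfig) -> RunReport:
    """Rebuild the report purely from serialized intermediates."""
    import pandas as pd

    out = Path(out_dir)
    missing = [f for f in ("model_table.tsv", "univariate.tsv")
               if not (out / f).exists()]
    missing += [
        f"{g1}_vs_{g2}/discriminants.tsv"
        for g1, g2 in cfg.comparisons
        if not (out / f"{g1}_vs_{g2}" / "discriminants.tsv").exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing intermediates: {missing}")
    model_table = pd.read_csv(out / "model_table.tsv", sep="\t")
    uni = pd.read_csv(out / "univariate.tsv", sep="\t")
    discs = {}
    for g1, g2 in cfg.comparisons:
        tag = f"{g1}_vs_{g2}"
        df = pd.read_csv(out / tag / "discriminants.tsv", sep="\t")
        if "metabolites" not in df.columns:  # empty selection writes no columns
            df["metabolites"] = pd.Series(dtype=str)
        discs[tag] = df
    report = RunReport(config=cfg, model_table=model_table, univariate=uni,
                       discriminants=discs, out_dir=out)
    (out / "report.md").write_text(report.render())
    return report
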