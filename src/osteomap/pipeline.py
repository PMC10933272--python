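"""End-to-end pipeline: simulate/load → orient → CSG → shape → thickness.

One YAML config drives the run; every output carries the seed and the
config hash so a run can be reproduced bit-for-bit.  Stages:

1. acquire specimens (synthetic population, or a manifest of labeled
   volumes + anatomical-point CSVs),
2. biomechanical orientation and length,
3. CSG series on the 20–80% grid and reliable-region screening of each
   specimen against the rest of the sample,
4. diaphyseal (and, for synthetic runs, proximal) landmark datasets →
   GPA → shape PCA → allometry permutation test,
5. relative-cortical-thickness matrices → PCA,
6. machine-readable JSON report + markdown twin.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import csg as csg_mod
from . import morphometrics as gm
from . import phantom as synth
from . import thickness as th
from .orientation import orient_bone, points_from_csv
from .volume import load_nifti

logger = logging.getLogger(__name__)


# -- configuration ---------------------------------------------------------


class SynthBlock(BaseModel):
    n_per_group: int = 5
    groups: dict[str, dict[str, float]] = Field(default_factory=lambda: {"A": {}})
    noise_sd: float = 0.1
    length_mm: float = 60.0
    shaft_curvature_mm: float = 2.0
    outer_radius_mm: float = 5.0
    cortical_thickness_mm: float = 2.0
    epiphysis_scale: float = 1.4
    voxel_spacing_mm: float = 0.3


class RangeBlock(BaseModel):
    from_fraction: float
    to_fraction: float
    step: float = 0.01
    k: int = 21


class CsgBlock(RangeBlock):
    from_fraction: float = 0.20
    to_fraction: float = 0.80
    threshold_z: float = 2.0


class MorphoBlock(RangeBlock):
    from_fraction: float = 0.50
    to_fraction: float = 0.70
    exclude: list[str] = Field(default_factory=list)
    permutations: int = 1000
    allometry_component: int = 0


class ThicknessBlock(RangeBlock):
    from_fraction: float = 0.53
    to_fraction: float = 0.65
    exclude: list[str] = Field(default_factory=list)


class RunConfig(BaseModel):
    seed: int = 0
    output_dir: str = "osteomap_run"
    manifest: Optional[str] = None
    synth: Optional[SynthBlock] = None
    csg: CsgBlock = Field(default_factory=CsgBlock)
    morpho: MorphoBlock = Field(default_factory=MorphoBlock)
    thickness: ThicknessBlock = Field(default_factory=ThicknessBlock)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        """Hash of the scientific configuration (where the run writes and how
        verbosely it logs do not change the results)."""
        payload = self.model_dump(exclude={"output_dir", "log_level"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: dict | RunConfig) -> list[str]:
    """Schema + semantic checks; returns human-readable findings (empty = ok)."""
    findings: list[str] = []
    if isinstance(config, dict):
        try:
            config = RunConfig.model_validate(config)
        except ValidationError as exc:
            return [f"schema: {e['loc']}: {e['msg']}" for e in exc.errors()]
    for name in ("csg", "morpho", "thickness"):
        block: RangeBlock = getattr(config, name)
        if block.step <= 0:
            findings.append(f"{name}.step must be positive, got {block.step}")
        if block.from_fraction > block.to_fraction:
            findings.append(
                f"{name}: range [{block.from_fraction}, {block.to_fraction}] is inverted"
            )
        if not (0 <= block.from_fraction <= 1 and 0 <= block.to_fraction <= 1):
            findings.append(f"{name}: fractions must lie in [0, 1]")
        if block.k < 3:
            findings.append(f"{name}.k must be at least 3, got {block.k}")
    if config.synth is None and config.manifest is None:
        findings.append("either a synth block or a manifest is required")
    if config.manifest is not None:
        mpath = Path(config.manifest)
        if not mpath.exists():
            findings.append(f"manifest file {config.manifest} does not exist")
        else:
            df = pd.read_csv(mpath)
            for col in ("specimen_id", "volume_file", "points_file"):
                if col not in df.columns:
                    findings.append(f"manifest lacks required column {col!r}")
            if not findings:
                for r in df.itertuples():
                    for f in (r.volume_file, r.points_file):
                        if not (mpath.parent / f).exists():
                            findings.append(f"specimen {r.specimen_id}: missing file {f}")
    if config.synth is not None and config.synth.n_per_group < 2:
        findings.append("synth.n_per_group must be at least 2")
    return findings


# -- report schema ---------------------------------------------------------


class StageStatus(BaseModel):
    status: str  # 'ok' | 'skipped' | 'failed'
    detail: str = ""


class Report(BaseModel):
    seed: int
    config_hash: str
    n_specimens: int
    groups: dict[str, int]
    stages: dict[str, StageStatus]
    counts: dict[str, int]
    reliable_regions: dict[str, tuple[float, float]]
    shape_pca_percent_variance: list[float]
    proximal_pca_percent_variance: list[float]
    thickness_pca_percent_variance: list[float]
    allometry: dict[str, float]


# -- specimen acquisition --------------------------------------------------


class _Specimen:
    def __init__(self, sid, volume, points, group, spec=None):
        self.id, self.volume, self.points, self.group, self.spec = (
            sid, volume, points, group, spec,
        )
        self.frame = None


def _acquire(config: RunConfig) -> list[_Specimen]:
    specimens: list[_Specimen] = []
    if config.synth is not None:
        s = config.synth
        base = synth.BonePhantomSpec(
            length_mm=s.length_mm,
            shaft_curvature_mm=s.shaft_curvature_mm,
            outer_radius_profile=s.outer_radius_mm,
            cortical_thickness_profile=s.cortical_thickness_mm,
            epiphysis_scale=s.epiphysis_scale,
            voxel_spacing_mm=s.voxel_spacing_mm,
        )
        pop = synth.generate_population(
            s.n_per_group, s.groups, s.noise_sd, config.seed, base_spec=base
        )
        counters: dict[str, int] = {}
        for vol, truth in pop:
            g = truth.group_label
            counters[g] = counters.get(g, 0) + 1
            sid = f"{g}{counters[g]:02d}"
            specimens.append(
                _Specimen(sid, vol, synth.anatomical_points(truth.spec), g, truth.spec)
            )
    else:
        mpath = Path(config.manifest)
        df = pd.read_csv(mpath)
        for r in df.itertuples():
            vol = load_nifti(str(mpath.parent / r.volume_file))
            pts = points_from_csv(str(mpath.parent / r.points_file))
            group = getattr(r, "group", "default")
            specimens.append(_Specimen(str(r.specimen_id), vol, pts, group))
    return specimens


# -- pipeline --------------------------------------------------------------


def run_pipeline(config: RunConfig) -> Report:
    """Execute all stages, write artifacts under ``config.output_dir``."""
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid configuration: " + "; ".join(findings))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)

    stages: dict[str, StageStatus] = {}
    counts: dict[str, int] = {}
    try:
        specimens = _acquire(config)
        stages["acquire"] = StageStatus(status="ok", detail=f"{len(specimens)} specimens")

        for sp in specimens:
            sp.frame = orient_bone(sp.volume, sp.points)
        stages["orient"] = StageStatus(status="ok")

        # CSG series and reliable-region screening
        cb = config.csg
        all_series = {}
        for sp in specimens:
            try:
                all_series[sp.id] = csg_mod.csg_series(
                    sp.volume, sp.frame, cb.from_fraction, cb.to_fraction, cb.step
                )
            except Exception as exc:
                raise RuntimeError(f"stage csg, specimen {sp.id}: {exc}") from exc
        counts["csg_sections_per_specimen"] = len(next(iter(all_series.values())))
        regions: dict[str, tuple[float, float]] = {}
        if len(specimens) >= 3:
            for sp in specimens:
                ref = [v for k, v in all_series.items() if k != sp.id]
                try:
                    regions[sp.id] = csg_mod.select_reliable_region(
                        all_series[sp.id], ref, cb.threshold_z
                    )
                except ValueError as exc:
                    # e.g. a specimen deviating from the pooled sample at every
                    # fraction: report the absence instead of aborting the run
                    logger.warning("reliable region for %s: %s", sp.id, exc)
        tidy = pd.concat(
            [csg_mod.series_to_dataframe(s, sid) for sid, s in all_series.items()]
        )
        tidy.to_csv(out / "csg_series.csv", index=False)
        stages["csg"] = StageStatus(status="ok")

        # diaphyseal shape analysis
        mb = config.morpho
        configs = []
        for sp in specimens:
            try:
                configs.append(
                    gm.build_diaphysis_dataset(
                        sp.volume, sp.frame, mb.from_fraction, mb.to_fraction,
                        mb.step, mb.k, specimen_id=sp.id,
                    )
                )
            except Exception as exc:
                raise RuntimeError(f"stage gm, specimen {sp.id}: {exc}") from exc
        counts["diaphysis_sections"] = int(
            round((mb.to_fraction - mb.from_fraction) / mb.step)
        ) + 1
        counts["diaphysis_semilandmarks"] = configs[0].points.shape[0]
        gpa_res = gm.gpa(configs)
        shape_pca = gm.pca(gpa_res, exclude=mb.exclude)
        pd.DataFrame(
            shape_pca.scores,
            index=shape_pca.specimen_ids,
            columns=[f"PC{i+1}" for i in range(shape_pca.scores.shape[1])],
        ).to_csv(out / "shape_scores.csv", index_label="specimen_id")
        kept = [i for i, sid in enumerate(gpa_res.specimen_ids) if sid in shape_pca.specimen_ids]
        slope, r2, pval = gm.allometry_test(
            shape_pca, gpa_res.centroid_sizes[kept],
            component=min(mb.allometry_component, shape_pca.scores.shape[1] - 1),
            n_permutations=mb.permutations, seed=config.seed,
        )
        stages["gm_diaphysis"] = StageStatus(status="ok")

        # proximal dataset (needs synthetic facet vertices)
        proximal_percent: list[float] = []
        if all(sp.spec is not None for sp in specimens):
            prox = [
                gm.build_proximal_dataset(
                    sp.volume, sp.frame, synth.proximal_facet_vertices(sp.spec),
                    k=mb.k, specimen_id=sp.id,
                )
                for sp in specimens
            ]
            prox_pca = gm.pca(gm.gpa(prox))
            proximal_percent = prox_pca.percent_variance.tolist()
            counts["proximal_points"] = prox[0].points.shape[0]
            stages["gm_proximal"] = StageStatus(status="ok")
        else:
            stages["gm_proximal"] = StageStatus(
                status="skipped", detail="no articular facet vertices available"
            )

        # thickness maps
        tb = config.thickness
        matrices = []
        for sp in specimens:
            try:
                matrices.append(
                    th.build_matrix(
                        sp.volume, sp.frame, tb.from_fraction, tb.to_fraction,
                        tb.step, tb.k, specimen_id=sp.id,
                    )
                )
            except Exception as exc:
                raise RuntimeError(f"stage thickness, specimen {sp.id}: {exc}") from exc
        counts["thickness_rows"] = matrices[0].values.shape[0]
        counts["thickness_cols"] = matrices[0].values.shape[1]
        th.matrices_to_long_csv(matrices, out / "thickness_long.csv")
        th_pca = th.pca_matrices(matrices, exclude=tb.exclude)
        pd.DataFrame(
            th_pca.scores,
            index=th_pca.specimen_ids,
            columns=[f"PC{i+1}" for i in range(th_pca.scores.shape[1])],
        ).to_csv(out / "thickness_scores.csv", index_label="specimen_id")
        stages["thickness"] = StageStatus(status="ok")
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    groups: dict[str, int] = {}
    for sp in specimens:
        groups[sp.group] = groups.get(sp.group, 0) + 1
    report = Report(
        seed=config.seed,
        config_hash=config.content_hash(),
        n_specimens=len(specimens),
        groups=groups,
        stages=stages,
        counts=counts,
        reliable_regions={k: (round(a, 6), round(b, 6)) for k, (a, b) in regions.items()},
        shape_pca_percent_variance=[round(v, 10) for v in shape_pca.percent_variance],
        proximal_pca_percent_variance=[round(v, 10) for v in proximal_percent],
        thickness_pca_percent_variance=[round(v, 10) for v in th_pca.percent_variance],
        allometry={"slope": slope, "r_squared": r2, "p_value": pval},
    )
    report_json = report.model_dump_json(indent=2)
    (out / "report.json").write_text(report_json)
    (out / "report.md").write_text(make_report(report))
    return report


def make_report(report: Report) -> str:
    """Markdown twin of the JSON report."""
    lines = [
        "# osteomap run report",
        "",
        f"- seed: {report.seed}",
        f"- config hash: `{report.config_hash}`",
        f"- specimens: {report.n_specimens} "
        + ", ".join(f"{g}: {n}" for g, n in sorted(report.groups.items())),
        "",
        "## Stages",
        "",
        "| stage | status | detail |",
        "|---|---|---|",
    ]
    for name, st in report.stages.items():
        lines.append(f"| {name} | {st.status} | {st.detail} |")
    lines += ["", "## Counts", ""]
    for k, v in report.counts.items():
        lines.append(f"- {k}: {v}")
    if report.reliable_regions:
        lines += ["", "## Reliable diaphyseal regions", ""]
        for sid, (lo, hi) in sorted(report.reliable_regions.items()):
            lines.append(f"- {sid}: [{lo:.2f}, {hi:.2f}]")

    def pv(title, values):
        if not values:
            return
        lines.append("")
        lines.append(f"## {title} — % variance")
        lines.append("")
        for i, v in enumerate(values[:5]):
            lines.append(f"- PC{i+1}: {v:.2f}%")

    pv("Diaphyseal shape PCA", report.shape_pca_percent_variance)
    pv("Proximal shape PCA", report.proximal_pca_percent_variance)
    pv("Thickness-map PCA", report.thickness_pca_percent_variance)
    a = report.allometry
    lines += [
        "",
        "## Allometry",
        "",
        f"slope = {a['slope']:.4g}, R² = {a['r_squared']:.4f}, p = {a['p_value']:.4g}",
        "",
    ]
    return "\n".join(lines)
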