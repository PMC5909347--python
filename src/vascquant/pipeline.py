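"""Pipeline orchestration: simulate -> quantify -> report.

Stages communicate through on-disk artifacts (NIfTI volumes, PNG images,
CSV tables, JSON ground truth) so each stage is independently testable
and resumable; a manifest with a config hash and per-file checksums makes
drift detectable.  An in-memory path (:func:`quantify_bundle`,
:func:`analyze_cohort`) runs the same computations on
:class:`~vascquant.phantoms.AnimalBundle` objects without touching disk,
which the statistical power analyses use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from vascquant import ct as ctq
from vascquant import dwi as dwiq
from vascquant import histo as hq
from vascquant import phantoms, stats

log = logging.getLogger("vascquant")

#: The four correlation analyses of the reporting stage:
#: (name, imaging variable, reference variable).
CORRELATION_PAIRS = (
    ("max_adc_perf_vs_mvd", "max_adc_perf", "mvd"),
    ("mean_adc_perf_vs_enhancement", "mean_adc_perf", "enhancement"),
    ("max_adc_diff_vs_necrotic_fraction", "max_adc_diff", "necrotic_fraction"),
    ("min_adc_diff_vs_mvd", "min_adc_diff", "mvd"),
)

#: Variables entering the group-comparison table, with summary modes
#: (ordinal TOF scores are reported mean +/- SD, the rest median (IQR)).
TABLE_VARIABLES = ("tumour_volume_cm3", "tof_score", "max_adc_diff",
                   "min_adc_diff", "max_adc_perf", "mean_adc_perf",
                   "mean_hu_pre", "mean_hu_post", "enhancement",
                   "necrotic_fraction", "mvd", "beads_per_fov")
SUMMARY_MODES = {"tof_score": "mean-sd"}


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end run."""

    out_dir: Path = Path("results/run")
    seed: int = 0
    n_per_group: int = 3
    noise_model: str = "rician"
    snr: float = 50.0
    ct_noise_sigma: float = 2.0
    dwi_grid_shape: tuple[int, int, int] = (12, 12, 6)
    ct_grid_shape: tuple[int, int, int] = (24, 24, 12)
    hu_limits: tuple[float, float] = (-50.0, 350.0)
    necrosis_threshold_hu: float = 50.0
    stain_threshold: float = 0.5
    min_structure_area: int = 3
    alpha: float = 0.050
    gate_force: str | None = None       # None | always-t | always-u

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        lo, hi = self.hu_limits
        if not lo < hi:
            raise ValueError("hu_limits must satisfy lo < hi")
        if self.gate_force not in (None, "always-t", "always-u"):
            raise ValueError(f"invalid gate_force {self.gate_force!r}")
        self.out_dir = Path(self.out_dir)

    def cohort_spec(self) -> phantoms.CohortSpec:
        return phantoms.CohortSpec(
            n_per_group=self.n_per_group, seed=self.seed,
            noise_model=self.noise_model, snr=self.snr,
            ct_noise_sigma=self.ct_noise_sigma,
            dwi_grid_shape=tuple(self.dwi_grid_shape),
            ct_grid_shape=tuple(self.ct_grid_shape))

    def config_hash(self) -> str:
        payload = {f.name: str(getattr(self, f.name))
                   for f in dataclasses.fields(self)}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, config: RunConfig, stage: str,
                   files: list[Path]) -> Path:
    from vascquant import __version__
    manifest = {
        "tool_version": __version__,
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "checksums": {str(p.relative_to(out_dir)): _sha256(p)
                      for p in sorted(files)},
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _save_nifti(array: np.ndarray, spacing, path: Path, dtype=np.float32) -> Path:
    affine = np.diag(list(np.asarray(spacing, float)) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=dtype), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate_cohort(config: RunConfig) -> Path:
    """Render the synthetic cohort to per-animal directories.

    Each animal directory holds the 4-D DWI stack, tissue/contour masks
    and CT volumes as NIfTI, histology/bead images as PNG, and a JSON
    ground-truth sidecar; a stage manifest records checksums.
    """
    config.validate()
    out = Path(config.out_dir) / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    bundles = phantoms.generate_cohort(config.cohort_spec())
    written: list[Path] = []
    for b in bundles:
        adir = out / b.animal_id
        adir.mkdir(exist_ok=True)
        stack: dwiq.BValueStack = b.dwi_stack
        written.append(_save_nifti(stack.signal, stack.voxel_spacing,
                                   adir / "dwi.nii.gz"))
        written.append(_save_nifti(b.tissue_map, stack.voxel_spacing,
                                   adir / "tissue_map.nii.gz", np.uint8))
        written.append(_save_nifti(b.tumour_mask, stack.voxel_spacing,
                                   adir / "tumour_mask.nii.gz", np.uint8))
        ct_spacing = (0.42, 0.42, 0.75)
        written.append(_save_nifti(b.ct_pre, ct_spacing, adir / "ct_pre.nii.gz"))
        written.append(_save_nifti(b.ct_post, ct_spacing, adir / "ct_post.nii.gz"))
        written.append(_save_nifti(b.ct_contour, ct_spacing,
                                   adir / "ct_contour.nii.gz", np.uint8))
        p = adir / "histology.png"
        iio.imwrite(p, (b.histology_image * 255).astype(np.uint8))
        written.append(p)
        for k, img in enumerate(b.bead_images):
            p = adir / f"beads_fov{k:02d}.png"
            iio.imwrite(p, (img * 255).astype(np.uint8))
            written.append(p)
        truth = {
            "animal_id": b.animal_id, "cell_line": b.cell_line,
            "group": b.group,
            "b_values": stack.b_values.tolist(),
            "voxel_spacing_mm": stack.voxel_spacing.tolist(),
            "ct_voxel_spacing_mm": list(ct_spacing),
            "necrotic_fraction": b.necrotic_fraction_truth,
            "mvd_truth_count": b.mvd_truth_count,
            "histology_pixel_size_um": b.histology_pixel_size,
            "bead_counts": b.bead_counts_truth,
            "tof_score": b.tof_score,
        }
        p = adir / "truth.json"
        p.write_text(json.dumps(truth, indent=2, sort_keys=True))
        written.append(p)
    write_manifest(out, config, "simulate", written)
    log.info("simulate: wrote %d animals to %s", len(bundles), out)
    return out


def _load_truth(adir: Path) -> dict:
    return json.loads((adir / "truth.json").read_text())


def _animal_dirs(cohort_dir: Path) -> list[Path]:
    dirs = sorted(p for p in Path(cohort_dir).iterdir() if p.is_dir())
    if not dirs:
        raise FileNotFoundError(f"no animal directories under {cohort_dir}")
    return dirs


# ---------------------------------------------------------------------------
# quantify (in-memory core + disk wrappers)
# ---------------------------------------------------------------------------

def quantify_dwi_stack(stack: dwiq.BValueStack, tumour_mask: np.ndarray) -> dict:
    """ROI statistics of ADC_diff and ADC_perf plus T2-style volumetry."""
    adc_diff = dwiq.compute_adc_diff(stack)
    adc_perf = dwiq.compute_adc_perf(stack)
    roi = dwiq.ROIMask(mask=tumour_mask, label="tumour",
                       voxel_spacing=stack.voxel_spacing, affine=stack.affine)
    sd = dwiq.roi_statistics(adc_diff, roi)
    sp = dwiq.roi_statistics(adc_perf, roi)
    return {
        "min_adc_diff": sd.minimum, "mean_adc_diff": sd.mean,
        "max_adc_diff": sd.maximum,
        "min_adc_perf": sp.minimum, "mean_adc_perf": sp.mean,
        "max_adc_perf": sp.maximum,
        "n_voxels": sd.n_voxels,
        "tumour_volume_cm3": dwiq.tumour_volume(roi),
    }


def quantify_ct_study(study: ctq.CTStudy, limits: ctq.HULimits,
                      necrosis_threshold: float) -> dict:
    m = ctq.contrast_enhancement(study, limits, necrosis_threshold)
    return {"mean_hu_pre": m.mean_pre, "mean_hu_post": m.mean_post,
            "enhancement": m.enhancement,
            "necrotic_fraction": m.necrotic_fraction,
            "total_necrosis_flag": m.total_necrosis_flag}


def quantify_histology(image: np.ndarray, pixel_size: float,
                       bead_images, params: hq.SegmentationParams) -> dict:
    slide = hq.StainedSlide(image=image, pixel_size=pixel_size)
    labels = hq.segment_stained_structures(slide, params)
    mvd = hq.microvessel_density(labels, pixel_size)
    fovs = [hq.StainedSlide(image=im, pixel_size=pixel_size)
            for im in bead_images]
    beads = hq.count_beads(
        fovs, hq.SegmentationParams(threshold=params.threshold,
                                    min_structure_area=params.min_structure_area,
                                    polarity="bright"))
    return {"mvd_count": mvd.count, "mvd_area_mm2": mvd.area, "mvd": mvd.density,
            "beads_per_fov": beads.mean_per_fov}


def quantify_bundle(bundle: phantoms.AnimalBundle,
                    config: RunConfig | None = None) -> dict:
    """All modality readouts for one in-memory animal bundle."""
    config = config or RunConfig()
    row = {"animal_id": bundle.animal_id, "cell_line": bundle.cell_line,
           "group": bundle.group, "tof_score": bundle.tof_score}
    row.update(quantify_dwi_stack(bundle.dwi_stack, bundle.tumour_mask))
    study = ctq.CTStudy(pre=bundle.ct_pre, post=bundle.ct_post,
                        contour=bundle.ct_contour)
    row.update(quantify_ct_study(study, ctq.HULimits(*config.hu_limits),
                                 config.necrosis_threshold_hu))
    if bundle.histology_image is not None:
        row.update(quantify_histology(
            bundle.histology_image, bundle.histology_pixel_size,
            bundle.bead_images,
            hq.SegmentationParams(threshold=config.stain_threshold,
                                  min_structure_area=config.min_structure_area)))
    return row


def analyze_cohort(bundles, config: RunConfig | None = None) -> pd.DataFrame:
    """Quantify every bundle in memory; one row per animal."""
    config = config or RunConfig()
    return pd.DataFrame([quantify_bundle(b, config) for b in bundles])


def _quantify_stage(config: RunConfig, modality: str) -> Path:
    """Shared disk-based quantification driver with per-animal isolation."""
    cohort_dir = Path(config.out_dir) / "cohort"
    rows, failed = [], []
    for adir in _animal_dirs(cohort_dir):
        try:
            truth = _load_truth(adir)
            row = {"animal_id": truth["animal_id"],
                   "cell_line": truth["cell_line"], "group": truth["group"]}
            if modality == "dwi":
                img = nib.load(str(adir / "dwi.nii.gz"))
                spacing = np.asarray(truth["voxel_spacing_mm"], float)
                stack = dwiq.BValueStack(
                    signal=np.asarray(img.dataobj, float),
                    b_values=np.asarray(truth["b_values"], float),
                    voxel_spacing=spacing)
                mask = np.asarray(
                    nib.load(str(adir / "tumour_mask.nii.gz")).dataobj) > 0
                row.update(quantify_dwi_stack(stack, mask))
            elif modality == "ct":
                pre = np.asarray(nib.load(str(adir / "ct_pre.nii.gz")).dataobj, float)
                post = np.asarray(nib.load(str(adir / "ct_post.nii.gz")).dataobj, float)
                contour = np.asarray(
                    nib.load(str(adir / "ct_contour.nii.gz")).dataobj) > 0
                study = ctq.CTStudy(
                    pre=pre, post=post, contour=contour,
                    voxel_spacing=np.asarray(truth["ct_voxel_spacing_mm"], float))
                row.update(quantify_ct_study(
                    study, ctq.HULimits(*config.hu_limits),
                    config.necrosis_threshold_hu))
            elif modality == "histo":
                himg = iio.imread(adir / "histology.png").astype(float) / 255.0
                bead_imgs = [iio.imread(p).astype(float) / 255.0
                             for p in sorted(adir.glob("beads_fov*.png"))]
                row["tof_score"] = truth["tof_score"]
                row.update(quantify_histology(
                    himg, truth["histology_pixel_size_um"], bead_imgs,
                    hq.SegmentationParams(threshold=config.stain_threshold,
                                          min_structure_area=config.min_structure_area)))
            else:
                raise ValueError(f"unknown modality {modality!r}")
            rows.append(row)
        except Exception:
            log.exception("%s quantification failed for %s", modality, adir.name)
            failed.append(adir.name)
    if not rows:
        raise RuntimeError(f"{modality}: every animal failed")
    out_csv = Path(config.out_dir) / f"quantify_{modality}.csv"
    pd.DataFrame(rows).to_csv(out_csv, index=False)
    write_manifest(Path(config.out_dir), config, f"quantify_{modality}", [out_csv])
    if failed:
        log.warning("%s: skipped animals %s", modality, failed)
    return out_csv


def quantify_dwi(config: RunConfig) -> Path:
    """ADC ROI statistics per animal -> quantify_dwi.csv."""
    return _quantify_stage(config, "dwi")


def quantify_ct(config: RunConfig) -> Path:
    """CT enhancement and necrotic fraction per animal -> quantify_ct.csv."""
    return _quantify_stage(config, "ct")


def quantify_histo(config: RunConfig) -> Path:
    """MVD and bead counts per animal -> quantify_histo.csv."""
    return _quantify_stage(config, "histo")


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def correlation_report(df: pd.DataFrame) -> pd.DataFrame:
    """The four imaging-vs-reference Spearman correlations.

    When a total-necrosis flag is present the necrotic-fraction
    correlation is rerun with the flagged animals excluded and both
    variants are reported.
    """
    rows = []
    flagged = tuple(df.loc[df.get("total_necrosis_flag", False) == True,  # noqa: E712
                           "animal_id"]) if "total_necrosis_flag" in df else ()
    for name, xvar, yvar in CORRELATION_PAIRS:
        res = stats.spearman(df[xvar], df[yvar])
        rows.append({"analysis": name, "x": xvar, "y": yvar,
                     "r": res.r, "p_value": res.p_value, "n": res.n,
                     "excluded": ""})
        if flagged and "necrotic_fraction" in (xvar, yvar):
            res2 = stats.spearman(df[xvar], df[yvar], ids=df["animal_id"],
                                  excluded_ids=flagged)
            rows.append({"analysis": name + "_excl_total_necrosis",
                         "x": xvar, "y": yvar, "r": res2.r,
                         "p_value": res2.p_value, "n": res2.n,
                         "excluded": ";".join(map(str, flagged))})
    return pd.DataFrame(rows)


def _tidy(df: pd.DataFrame, variables) -> pd.DataFrame:
    return df.melt(id_vars=["animal_id", "cell_line", "group"],
                   value_vars=[v for v in variables if v in df.columns],
                   var_name="variable", value_name="value")


def report(config: RunConfig, make_figures: bool = True) -> dict:
    """Assemble the cohort comparison table and correlation analyses.

    Requires all three quantify stages; merges their per-animal rows,
    builds the stratified comparison table (chi-square for the ordinal
    TOF scores, gated t/U tests elsewhere), the four Spearman
    correlations with the exclusion-rerun variant, and scatter figures.
    """
    out = Path(config.out_dir)
    paths = {m: out / f"quantify_{m}.csv" for m in ("dwi", "ct", "histo")}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing quantify outputs: {missing}")
    keys = ["animal_id", "cell_line", "group"]
    df = pd.read_csv(paths["dwi"])
    for m in ("ct", "histo"):
        df = df.merge(pd.read_csv(paths[m]), on=keys, how="inner")
    if df.empty:
        raise RuntimeError("empty cohort after merging quantify outputs")
    return report_from_frame(df, config, out_dir=out,
                             make_figures=make_figures)


def report_from_frame(df: pd.DataFrame, config: RunConfig | None = None,
                      out_dir: Path | None = None,
                      make_figures: bool = False) -> dict:
    """Reporting stage on an in-memory per-animal table."""
    config = config or RunConfig()
    variables = [v for v in TABLE_VARIABLES
                 if v in df.columns and v != "tof_score"]
    table = stats.build_comparison_table(
        _tidy(df, variables), alpha=config.alpha,
        modes=SUMMARY_MODES, force=config.gate_force)

    # ordinal TOF scores: chi-square per stratum, summarised mean +/- SD
    tof_rows = []
    if "tof_score" in df.columns:
        for stratum in list(df["cell_line"].unique()) + ["merged"]:
            ds = df if stratum == "merged" else df[df["cell_line"] == stratum]
            groups = sorted(ds["group"].unique())
            a = ds[ds["group"] == groups[0]]["tof_score"].astype(int)
            b = ds[ds["group"] == groups[1]]["tof_score"].astype(int)
            res = stats.chi_square_ordinal(a, b, alpha=config.alpha)
            tof_rows.append({
                "variable": "tof_score", "cell_line": stratum,
                f"summary_{groups[0]}": str(stats.summarize(a, "mean-sd")),
                f"summary_{groups[1]}": str(stats.summarize(b, "mean-sd")),
                "summary_mode": "mean-sd", "test": res.test_name,
                "statistic": res.statistic, "p_value": res.p_value,
                "significant": res.significant, "gate": "",
                "n_" + groups[0]: a.size, "n_" + groups[1]: b.size})
    if tof_rows:
        table = pd.concat([table, pd.DataFrame(tof_rows)], ignore_index=True)

    correlations = correlation_report(df)

    result = {"comparison_table": table, "correlations": correlations}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = []
        p = out_dir / "comparison_table.csv"
        table.to_csv(p, index=False)
        files.append(p)
        p = out_dir / "correlations.csv"
        correlations.to_csv(p, index=False)
        files.append(p)
        p = out_dir / "correlations.json"
        p.write_text(correlations.to_json(orient="records", indent=2))
        files.append(p)
        if make_figures:
            files += _correlation_figures(df, out_dir)
        if config is not None:
            write_manifest(out_dir, config, "report", files)
        result["out_dir"] = out_dir
    return result


def _correlation_figures(df: pd.DataFrame, out_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    paths = []
    for name, xvar, yvar in CORRELATION_PAIRS:
        fig, ax = plt.subplots(figsize=(4, 4))
        for group, marker in (("co", "o"), ("non-co", "s")):
            d = df[df["group"] == group]
            ax.scatter(d[xvar], d[yvar], marker=marker, label=group, alpha=0.8)
        res = stats.spearman(df[xvar], df[yvar])
        ax.set_xlabel(xvar)
        ax.set_ylabel(yvar)
        ax.set_title(f"Spearman r = {res.r:.3f}, p = {res.p_value:.3g}")
        ax.legend()
        fig.tight_layout()
        p = out_dir / f"fig_{name}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths


def run_all(config: RunConfig) -> dict:
    """simulate -> quantify all modalities -> report."""
    simulate_cohort(config)
    quantify_dwi(config)
    quantify_ct(config)
    quantify_histo(config)
    return report(config)
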