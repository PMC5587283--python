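"""End-to-end runs: generate -> measure -> compare -> report.

A run is driven by one JSON-serializable :class:`RunConfig`.  Three
source modes cover the ways a cohort can enter the pipeline:

* ``synthetic_cohort`` — skip imagery; draw per-image metric values for
  every group from the cohort defaults (fastest, for statistics work).
* ``synthetic_images`` — render longitudinal and cross-section images
  per group with generator parameters drawn from the group's metric
  distributions, then measure them like real data.
* ``images`` — read a manifest CSV of real TIFFs (columns ``path, kind,
  genotype, age_months, region``) and measure them.

Every stage appends structured log lines (stage, image id, status,
duration) to stderr and ``run.log``; outputs are ``metrics.csv``,
``comparisons.csv``, ``summary.csv``, figures, and a ``manifest.json``
recording the config hash, software version and every file touched, so
a run can be audited and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohorts import default_group_params
from .errors import ConfigurationError, DiamicroError
from .io import CalibratedImage, read_image, write_ground_truth, write_image
from .longitudinal import count_branched_fibers, interstitial_ratio, profile_along_line
from .sarcomere import SarcomereBand, estimate_sarcomere_length
from .sections import measure_section
from .stats import CohortComparisons
from .synthesize import (
    AGES_MONTHS,
    GENOTYPES,
    REGIONS,
    CrossSectionSpec,
    StriationSpec,
    generate_cross_section,
    generate_striation_image,
    sample_cohort,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "render_report",
            "measure_longitudinal_image"]

_ALL_GROUPS = [
    {"genotype": g, "age_months": a, "region": r}
    for g in GENOTYPES for a in AGES_MONTHS for r in REGIONS
]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run_out"
    alpha: float = 0.05
    family: str = "per_metric"
    band_um: tuple[float, float] = (1.5, 4.5)
    channels: dict[str, int] = field(
        default_factory=lambda: {"laminin": 0, "nuclei": 1, "cd68": 2}
    )
    source: dict = field(
        default_factory=lambda: {"mode": "synthetic_cohort", "n_per_group": 6}
    )
    groups: list[dict] = field(default_factory=lambda: list(_ALL_GROUPS))

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha: must lie in (0, 1)")
        mode = self.source.get("mode")
        if mode not in ("synthetic_cohort", "synthetic_images", "images"):
            raise ConfigurationError(f"source.mode: unknown mode {mode!r}")
        if mode == "images":
            if "manifest_csv" not in self.source:
                raise ConfigurationError("source.manifest_csv: required in images mode")
            if "pixel_size_um" not in self.source:
                raise ConfigurationError("source.pixel_size_um: required in images mode")
            if not self.channels:
                raise ConfigurationError("channels: required for section images")
            for role in ("laminin", "nuclei", "cd68"):
                if role not in self.channels:
                    raise ConfigurationError(f"channels.{role}: missing channel role")
        for grp in self.groups:
            for key in ("genotype", "age_months", "region"):
                if key not in grp:
                    raise ConfigurationError(f"groups[].{key}: missing field")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        if "band_um" in raw:
            raw = {**raw, "band_um": tuple(raw["band_um"])}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_um"] = list(d["band_um"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Audit record: what ran, from what, producing what."""

    config_hash: str
    software_version: str
    seed: int
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path


class _Log:
    def __init__(self, path: Path):
        self._fh = open(path, "w")

    def __call__(self, stage: str, image_id: str, status: str, t0: float) -> None:
        line = f"[{stage}] id={image_id} status={status} duration={time.perf_counter() - t0:.3f}s"
        print(line, file=sys.stderr)
        self._fh.write(line + "\n")

    def close(self) -> None:
        self._fh.close()


def measure_longitudinal_image(image: CalibratedImage, band: SarcomereBand):
    """(sarcomere_length_um | None, interstitial_ratio, percent_branched)."""
    try:
        est = estimate_sarcomere_length(image, band)
        sarc = est.modal_length_um
        orient = est.peak_orientation_deg
    except DiamicroError:
        sarc, orient = None, None
    from .longitudinal import fiber_mask_from_banded

    mask = fiber_mask_from_banded(image, orientation_deg=orient)
    profile = profile_along_line(mask, orientation_deg=orient)
    ratio = interstitial_ratio(profile)
    branch = count_branched_fibers(mask)
    return sarc, ratio, branch.percent_branched


def _truncated_draw(rng, mu, sd, lo=0.0, hi=np.inf):
    for _ in range(100):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mu, lo), hi))


def _generate_and_measure(cfg: RunConfig, out: Path, log: _Log, manifest: RunManifest) -> pd.DataFrame:
    """synthetic_images mode: render per-group images, measure them."""
    src = cfg.source
    band = SarcomereBand(*cfg.band_um)
    params = default_group_params()
    rng = np.random.default_rng(cfg.seed)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    stri_over = src.get("striation", {})
    sect_over = src.get("section", {})
    n_long = int(src.get("n_longitudinal", 2))
    n_sect = int(src.get("n_section", 2))
    rows = []
    written: list[str] = []
    for grp in cfg.groups:
        key = (grp["genotype"], grp["age_months"], grp["region"])
        p = params[key]
        gid = f"{key[0]}_{key[1]}m_{key[2]}"
        for i in range(n_long):
            t0 = time.perf_counter()
            image_id = f"{gid}_long{i:03d}"
            period = _truncated_draw(rng, *p["sarcomere_length_um"],
                                     lo=band.min_length_um + 0.05, hi=band.max_length_um - 0.05)
            gap = _truncated_draw(rng, *p["interstitial_ratio"], lo=0.05, hi=1.0)
            bfrac = _truncated_draw(rng, p["percent_branched"][0] / 100,
                                    p["percent_branched"][1] / 100, lo=0.0, hi=0.9)
            spec = StriationSpec(
                period_um=period, gap_to_fiber_ratio=gap, branch_fraction=bfrac,
                seed=int(rng.integers(2**31)),
                **{k: tuple(v) if k == "image_shape" else v for k, v in stri_over.items()},
            )
            img, truth = generate_striation_image(spec)
            write_image(img_dir / f"{image_id}.tif", img)
            write_ground_truth(img_dir / f"{image_id}.truth.json", truth)
            written.append(f"images/{image_id}.tif")
            sarc, ratio, pct = measure_longitudinal_image(img, band)
            if sarc is not None:
                rows.append((*key, image_id, "sarcomere_length_um", sarc))
            rows.append((*key, image_id, "interstitial_ratio", ratio))
            rows.append((*key, image_id, "percent_branched", pct))
            log("measure", image_id, "ok", t0)
        for i in range(n_sect):
            t0 = time.perf_counter()
            image_id = f"{gid}_sect{i:03d}"
            sect_shape = tuple(sect_over.get("image_shape", (384, 384)))
            sect_px = float(sect_over.get("pixel_size_um", 0.5))
            sect_n = int(sect_over.get("n_fibers", 24))
            csa_cap = 0.9 * sect_shape[0] * sect_shape[1] * sect_px**2 / sect_n
            csa = _truncated_draw(rng, *p["csa_um2"], lo=150.0, hi=csa_cap)
            cfrac = _truncated_draw(rng, p["percent_regenerating"][0] / 100,
                                    p["percent_regenerating"][1] / 100, lo=0.0, hi=1.0)
            dens = _truncated_draw(rng, *p["macrophage_density_per_mm2"], lo=0.0)
            sect_kwargs = dict(
                n_fibers=24, pixel_size_um=0.5, image_shape=(384, 384),
            )
            sect_kwargs.update({k: tuple(v) if k == "image_shape" else v for k, v in sect_over.items()})
            spec = CrossSectionSpec(
                csa_mean_um2=csa, central_nucleus_fraction=cfrac,
                macrophage_density_per_mm2=dens, seed=int(rng.integers(2**31)),
                **sect_kwargs,
            )
            img, truth = generate_cross_section(spec)
            write_image(img_dir / f"{image_id}.tif", img)
            write_ground_truth(img_dir / f"{image_id}.truth.json", truth)
            written.append(f"images/{image_id}.tif")
            rep = measure_section(img)
            rows.append((*key, image_id, "csa_um2", float(np.mean(rep.fiber_areas_um2))))
            rows.append((*key, image_id, "percent_regenerating", rep.percent_regenerating))
            rows.append((*key, image_id, "macrophage_density_per_mm2",
                         rep.macrophage_density_per_mm2))
            log("measure", image_id, "ok", t0)
    manifest.stages["generate"] = {"inputs": [], "outputs": written}
    return pd.DataFrame(rows, columns=["genotype", "age_months", "region",
                                       "image_id", "metric", "value"])


def _measure_real_images(cfg: RunConfig, log: _Log, manifest: RunManifest) -> pd.DataFrame:
    src = cfg.source
    band = SarcomereBand(*cfg.band_um)
    man = pd.read_csv(src["manifest_csv"])
    need = {"path", "kind", "genotype", "age_months", "region"}
    if not need <= set(man.columns):
        raise ConfigurationError(f"manifest_csv: needs columns {sorted(need)}")
    px = float(src["pixel_size_um"])
    rows = []
    root = Path(src["manifest_csv"]).parent
    for _, rec in man.iterrows():
        t0 = time.perf_counter()
        path = Path(rec["path"])
        if not path.is_absolute():
            path = root / path
        image_id = path.stem
        key = (rec["genotype"], int(rec["age_months"]), rec["region"])
        try:
            if rec["kind"] == "longitudinal":
                img = read_image(path, pixel_size_um=px)
                sarc, ratio, pct = measure_longitudinal_image(img, band)
                if sarc is not None:
                    rows.append((*key, image_id, "sarcomere_length_um", sarc))
                rows.append((*key, image_id, "interstitial_ratio", ratio))
                rows.append((*key, image_id, "percent_branched", pct))
            elif rec["kind"] == "section":
                img = read_image(path, pixel_size_um=px, channels=cfg.channels)
                rep = measure_section(img)
                rows.append((*key, image_id, "csa_um2", float(np.mean(rep.fiber_areas_um2))))
                rows.append((*key, image_id, "percent_regenerating", rep.percent_regenerating))
                rows.append((*key, image_id, "macrophage_density_per_mm2",
                             rep.macrophage_density_per_mm2))
            else:
                raise ConfigurationError(f"manifest kind: unknown kind {rec['kind']!r}")
        except DiamicroError as exc:
            log("measure", image_id, f"failed ({exc})", t0)
            raise type(exc)(f"stage=measure file={path}: {exc}") from exc
        log("measure", image_id, "ok", t0)
    manifest.stages["measure"] = {"inputs": [str(src["manifest_csv"])], "outputs": []}
    return pd.DataFrame(rows, columns=["genotype", "age_months", "region",
                                       "image_id", "metric", "value"])


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages of a run; returns the written manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    manifest = RunManifest(
        config_hash=config.config_hash(), software_version=__version__,
        seed=config.seed, config=config.to_dict(),
    )
    try:
        mode = config.source["mode"]
        t0 = time.perf_counter()
        if mode == "synthetic_cohort":
            from .cohorts import default_cohort_spec

            spec = default_cohort_spec(
                n_per_group=int(config.source.get("n_per_group", 6)),
                seed=config.seed,
                pooled_only=bool(config.source.get("pooled_only", False)),
            )
            table = sample_cohort(spec)
            keep = pd.MultiIndex.from_frame(
                pd.DataFrame(config.groups)[["genotype", "age_months", "region"]]
            )
            idx = pd.MultiIndex.from_frame(table[["genotype", "age_months", "region"]])
            table = table[idx.isin(keep)].reset_index(drop=True)
            manifest.stages["generate"] = {"inputs": [], "outputs": ["metrics.csv"]}
            log("generate", "cohort", "ok", t0)
        elif mode == "synthetic_images":
            table = _generate_and_measure(config, out, log, manifest)
        else:
            table = _measure_real_images(config, log, manifest)

        table.to_csv(out / "metrics.csv", index=False)

        t0 = time.perf_counter()
        results = CohortComparisons(table).fit(alpha=config.alpha, family=config.family)
        results.to_csv(out)
        (out / "report.txt").write_text(results.summary() + "\n")
        manifest.stages["stats"] = {
            "inputs": ["metrics.csv"],
            "outputs": ["comparisons.csv", "summary.csv", "report.txt"],
        }
        log("stats", "-", "ok", t0)

        t0 = time.perf_counter()
        figs, _ = render_report(results.summaries, results.comparisons,
                                alpha=config.alpha, out_dir=out / "figures")
        manifest.stages["report"] = {
            "inputs": ["summary.csv", "comparisons.csv"],
            "outputs": [f"figures/{m}.png" for m in figs],
        }
        log("report", "-", "ok", t0)
        manifest.write(out / "manifest.json")
    finally:
        log.close()
    return manifest


def render_report(summaries: pd.DataFrame, comparisons: pd.DataFrame,
                  alpha: float = 0.05, out_dir=None):
    """Grouped mean +/- SD bar panels per metric with significance markers.

    Returns ``(figures, markers)``: one matplotlib Figure per metric
    (panel A grouped by region, panel B by age) and the list of
    significant comparisons annotated, ``(metric, group_a, group_b)``.
    Empty summaries produce no figures (with a warning).
    """
    import warnings

    from matplotlib.figure import Figure

    if summaries is None or len(summaries) == 0:
        warnings.warn("empty summary table: nothing to plot")
        return {}, []
    markers = [
        (r.metric, r.group_a, r.group_b)
        for r in comparisons.itertuples()
        if r.adjusted_p < alpha
    ] if comparisons is not None and len(comparisons) else []
    sig_metrics = {m for m, _, _ in markers}
    figures = {}
    for metric, sub in summaries.groupby("metric", observed=True):
        fig = Figure(figsize=(10, 4))
        axes = fig.subplots(1, 2)
        for ax, by in zip(axes, ("region", "age_months")):
            cats = sorted(sub[by].unique(), key=str)
            width = 0.8 / max(1, sub.groupby(["genotype", "age_months" if by == "region" else "region"], observed=True).ngroups)
            offset = 0.0
            for (g, other), gsub in sub.groupby(
                ["genotype", "age_months" if by == "region" else "region"], observed=True
            ):
                xs, ys, es = [], [], []
                for k, cat in enumerate(cats):
                    row = gsub[gsub[by] == cat]
                    if len(row):
                        xs.append(k + offset)
                        ys.append(float(row["mean"].iloc[0]))
                        es.append(float(row["sd"].iloc[0]))
                ax.bar(xs, ys, width=width, yerr=es, capsize=2, label=f"{g} {other}")
                offset += width
            ax.set_xticks(range(len(cats)))
            ax.set_xticklabels([str(c) for c in cats])
            ax.set_xlabel(by)
            ax.set_title(f"{metric} by {by}" + ("  *" if metric in sig_metrics else ""))
            ax.legend(fontsize=6)
        if metric in sig_metrics:
            axes[0].annotate("*", xy=(0.02, 0.95), xycoords="axes fraction", fontsize=14)
        figures[metric] = fig
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            fig.savefig(out_dir / f"{metric}.png", dpi=100)
    return figures, markers
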