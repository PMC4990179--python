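"""End-to-end orchestration: regions -> coverage -> normalisation -> profiles.

``run_pipeline`` wires the stages together for every experiment in the
design sheet and every region group, and writes the profile table, the
metagene plot, optional pseudometric / permutation reports and a metadata
file that suffices to reproduce the run (inputs, settings, seed, and the
background ratio estimated per experiment).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignments import region_coverage
from .design import parse_design
from .inference import dissimilarity_from_similarity, permutation_test
from .normalization import ncis_ratio, rpm_normalize, subtract_background
from .profiles import (
    CoverageMatrix,
    bin_matrix,
    bootstrap_ribbon,
    profile_table,
)
from .regions import (
    RegionGroup,
    orient_region_coverage,
    read_bed,
    read_chrom_sizes,
    read_narrowpeak,
    resize_regions,
    stratify_by_score,
)
from .similarity import compute_all, ratio_intersect

log = logging.getLogger(__name__)

#: curve colours for up to four activity groups (none/low/moderate/high)
DEFAULT_COLORS = ("red", "green", "blue", "purple")


@dataclass
class AnalysisConfig:
    """Settings of one metagene analysis; every field is a config-file key."""

    regions: list[str] = field(default_factory=list)  # one group per file
    design: str = ""
    chrom_sizes: str = ""
    flank: int = 1000
    bin_size: int = 10
    estimator: str = "mean"
    bootstrap: int = 1000  # B
    level: float = 95.0
    permutations: int = 0  # 0 = skip permutation tests
    ncis_bin_size: int = 1000
    seed: int = 42
    stratify: bool = False  # split the single region file by score
    extend: int | None = None
    metrics: bool = True
    out: str = "metagene"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("regions", "design", "chrom_sizes"):
            if not getattr(self, name):
                raise ValueError(f"config is missing required input {name!r}")
        if self.flank <= 0 or self.bin_size < 1 or self.bootstrap < 2:
            raise ValueError("flank must be > 0, bin_size >= 1, bootstrap >= 2")
        if not (0 < self.level < 100):
            raise ValueError("level must be in (0, 100)")


def _read_region_file(path) -> RegionGroup:
    text = str(path).lower()
    if text.endswith((".narrowpeak", ".broadpeak")):
        return read_narrowpeak(path)
    return read_bed(path)


def load_region_groups(config: AnalysisConfig) -> list[RegionGroup]:
    groups = [_read_region_file(p) for p in config.regions]
    if config.stratify:
        if len(groups) != 1:
            raise ValueError("stratification expects exactly one region file")
        groups = list(stratify_by_score(groups[0]).values())
    return groups


def build_group_matrix(
    group: RegionGroup,
    chip_files: list[str],
    control_files: list[str],
    r_hat: float | None,
    experiment: str,
    extend: int | None = None,
) -> CoverageMatrix:
    """Merged, background-subtracted, RPM-scaled, 5'->3'-oriented matrix."""
    from .design import merge_replicates

    chip = merge_replicates(
        [region_coverage(f, group, extend=extend) for f in chip_files]
    )
    control = None
    if control_files and r_hat is not None:
        control = merge_replicates(
            [region_coverage(f, group, extend=extend) for f in control_files]
        )
    rows = []
    for i, region in enumerate(group):
        vec = chip.dense(i).astype(float)
        if control is not None:
            vec = subtract_background(vec, control.dense(i), r_hat)
        vec = rpm_normalize(vec, chip.library_size)
        rows.append(orient_region_coverage(vec, region.strand))
    return CoverageMatrix(
        values=np.vstack(rows),
        group_label=group.label,
        experiment=experiment,
        units="RPM",
        oriented=True,
    )


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis; returns the output paths and profiles."""
    config.validate()
    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    groups = [
        resize_regions(g, config.flank, chrom_sizes) for g in load_region_groups(config)
    ]
    design = parse_design(config.design)
    out = Path(config.out)
    out.parent.mkdir(parents=True, exist_ok=True)

    profiles = []
    matrices: dict[tuple[str, str], CoverageMatrix] = {}
    r_hats: dict[str, float | None] = {}
    for exp in design.experiments:
        chip_files = design.chip_files(exp)
        control_files = design.control_files(exp)
        r_hat = None
        if control_files:
            # pooled binned counts across replicates of each role
            from .normalization import bin_genome_counts

            chip_bins = sum(
                bin_genome_counts(f, chrom_sizes, config.ncis_bin_size) for f in chip_files
            )
            ctrl_bins = sum(
                bin_genome_counts(f, chrom_sizes, config.ncis_bin_size)
                for f in control_files
            )
            r_hat = ncis_ratio(chip_bins, ctrl_bins, bin_size=config.ncis_bin_size).r_hat
            log.info("experiment %s: NCIS r_hat = %.4f", exp, r_hat)
        else:
            log.warning("experiment %s has no control; skipping background removal", exp)
        r_hats[exp] = r_hat
        for group in groups:
            m = build_group_matrix(
                group, chip_files, control_files, r_hat, exp, extend=config.extend
            )
            m = bin_matrix(m, config.bin_size)
            matrices[(exp, group.label)] = m
            profiles.append(
                bootstrap_ribbon(
                    m,
                    estimator=config.estimator,
                    B=config.bootstrap,
                    level=config.level,
                    seed=config.seed,
                )
            )
            log.info(
                "experiment %s group %s: %d regions x %d bins",
                exp, group.label, m.n_regions, m.n_positions,
            )

    table = profile_table(profiles, flank=config.flank)
    profile_path = out.with_name(out.name + "_profiles.tsv")
    table.to_csv(profile_path, sep="\t", index=False, float_format="%.10g")

    plot_path = out.with_name(out.name + "_metagene.png")
    plot_metagene(profiles, plot_path, flank=config.flank)

    outputs = {
        "profiles": profiles,
        "matrices": matrices,
        "r_hats": r_hats,
        "profile_table": profile_path,
        "plot": plot_path,
    }

    if config.metrics and len(groups) > 1:
        outputs["metric_report"] = _metric_report(profiles, out)
    if config.permutations > 0 and len(groups) > 1:
        outputs["permutation_report"] = _permutation_report(matrices, design, groups, config, out)

    meta_path = out.with_name(out.name + "_metadata.yaml")
    with open(meta_path, "w") as fh:
        yaml.safe_dump(
            {
                "metaprofiler_version": __version__,
                "config": asdict(config),
                "r_hat": r_hats,
                "groups": {g.label: len(g) for g in groups},
                "region_width": 2 * config.flank,
            },
            fh,
            sort_keys=False,
        )
    outputs["metadata"] = meta_path
    return outputs


def _metric_report(profiles, out: Path) -> Path:
    rows = []
    by_exp: dict[str, list] = {}
    for p in profiles:
        by_exp.setdefault(p.experiment, []).append(p)
    for exp, plist in by_exp.items():
        for i in range(len(plist)):
            for j in range(i + 1, len(plist)):
                a, b = plist[i], plist[j]
                for name, res in compute_all(a.curve, b.curve).items():
                    rows.append(
                        {
                            "experiment": exp,
                            "group_a": a.group_label,
                            "group_b": b.group_label,
                            "metric": name,
                            "value": res.value if res.defined else "",
                            "defined": res.defined,
                            "reason": res.undefined_reason or "",
                        }
                    )
    path = out.with_name(out.name + "_metrics.tsv")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def _permutation_report(matrices, design, groups, config: AnalysisConfig, out: Path) -> Path:
    metric = dissimilarity_from_similarity(ratio_intersect, name="one_minus_ratio_intersect")
    rows = []
    for exp in design.experiments:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                mA = matrices[(exp, groups[i].label)]
                mB = matrices[(exp, groups[j].label)]
                res = permutation_test(
                    mA, mB, metric=metric, N=config.permutations,
                    seed=config.seed, estimator=config.estimator,
                )
                rows.append(
                    {
                        "experiment": exp,
                        "group_a": groups[i].label,
                        "group_b": groups[j].label,
                        "metric": res.metric_name,
                        "observed": res.observed,
                        "N": res.N,
                        "p_value": res.p_value,
                        "seed": config.seed,
                    }
                )
    path = out.with_name(out.name + "_permutations.tsv")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def plot_metagene(profiles, path, flank: int | None = None, colors=None) -> Path:
    """One curve plus translucent ribbon per group; x in bp from center."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not profiles:
        raise ValueError("no profiles to plot")
    widths = {len(p.curve) for p in profiles}
    if len(widths) != 1:
        raise ValueError(f"profiles have mismatched curve lengths: {sorted(widths)}")
    colors = list(colors or DEFAULT_COLORS)
    while len(colors) < len(profiles):
        colors += [None]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for p, color in zip(profiles, colors):
        n = len(p.curve)
        x = np.arange(n) * p.bin_size - (flank if flank is not None else 0)
        label = f"{p.experiment}:{p.group_label}" if p.experiment else p.group_label
        (line,) = ax.plot(x, p.curve, label=label, color=color)
        ax.fill_between(x, p.ribbon_low, p.ribbon_high, alpha=0.25, color=line.get_color())
    ax.set_xlabel("position relative to region center (bp)")
    ax.set_ylabel(f"coverage ({profiles[0].units})")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def export_heatmap_matrix(m: CoverageMatrix, path, order: str = "total", image=None) -> Path:
    """Write the regions x bins matrix as TSV, optionally with a PNG heatmap.

    ``order="total"`` sorts rows by total coverage descending (highest-sum
    region first); ``order="input"`` keeps the region order of the input.
    """
    if m.values.size == 0:
        raise ValueError("cannot export an empty matrix")
    if order not in ("total", "input"):
        raise ValueError("order must be 'total' or 'input'")
    values = m.values
    if order == "total":
        values = values[np.argsort(-values.sum(axis=1), kind="stable")]
    df = pd.DataFrame(values, columns=[f"bin_{i}" for i in range(values.shape[1])])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if image is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(values, aspect="auto", interpolation="nearest", cmap="viridis")
        fig.colorbar(im, ax=ax, label=m.units)
        ax.set_xlabel("bin")
        ax.set_ylabel("region")
        fig.tight_layout()
        fig.savefig(image, dpi=120)
        plt.close(fig)
    return Path(path)
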