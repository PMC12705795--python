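"""Model/Results interface for the full pre/post ROC analysis.

:class:`PrePostSDT` wraps a validated ratings table; :meth:`PrePostSDT.fit`
runs the whole battery -- per-participant AUC and B"D, complete-dataset and
per-set paired t-tests with JZS Bayes factors, the two 2x2 mixed ANOVAs with
generalized eta-squared and Monte-Carlo Bayes factors, the per-category
mean-ratings tests, and the group-average ROC export -- and returns a
:class:`PrePostSDTResults` carrying every table plus a ``summary()`` text
report and a ``save()`` that writes the TSV/JSON report bundle with a
reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, inference, io_model, roc
from .exceptions import ComputationError
from .io_model import RatingsTable

logger = logging.getLogger(__name__)


class PrePostSDT:
    """Signal-detection analysis model for a pre/post truth-rating table."""

    def __init__(
        self,
        table: RatingsTable,
        rscale: float = inference.DEFAULT_RSCALE,
        anova_bf_iterations: int = 10_000,
    ):
        self.table = table
        self.rscale = float(rscale)
        self.anova_bf_iterations = int(anova_bf_iterations)

    @classmethod
    def from_csv(cls, path: str | Path, scale_max: int = 7, **kwargs) -> "PrePostSDT":
        return cls(io_model.read_ratings_csv(path, scale_max=scale_max), **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        scale_max: int = 7,
        metadata: dict | None = None,
        **kwargs,
    ) -> "PrePostSDT":
        return cls(RatingsTable(data, scale_max=scale_max, metadata=metadata or {}), **kwargs)

    def fit(self, seed: int = 0, compute_anova_bf: bool = True) -> "PrePostSDTResults":
        """Run the full analysis; ``seed`` drives the ANOVA Bayes factors."""
        table = self.table
        logger.info("summarising %d participants", table.n_participants)
        sdt = roc.summarize(table)
        wide = sdt.pivot(index="participant_id", columns="phase", values=["auc", "bias"])
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        if wide.isna().any().any():
            missing = wide[wide.isna().any(axis=1)].index[0]
            raise ComputationError(f"participant {missing!r} lacks one phase")
        sets = sdt.drop_duplicates("participant_id").set_index("participant_id")["set"]
        wide["set"] = sets

        def contrast(measure: str, mask=None) -> inference.TestResult:
            sub = wide if mask is None else wide[mask]
            return inference.paired_t(
                sub[f"{measure}_pre"], sub[f"{measure}_post"], rscale=self.rscale
            )

        logger.info("complete-dataset and per-set paired tests")
        overall = {m: contrast(m) for m in ("auc", "bias")}
        per_set = {
            (m, s): contrast(m, wide["set"] == s)
            for m in ("auc", "bias")
            for s in ("A", "B")
            if (wide["set"] == s).any()
        }

        logger.info("2x2 mixed ANOVAs")
        anovas: dict[str, inference.AnovaResult] = {}
        anova_bf: dict[str, pd.DataFrame] = {}
        rng = np.random.default_rng(seed)
        for m in ("auc", "bias"):
            anovas[m] = inference.mixed_anova_2x2(
                wide[f"{m}_pre"], wide[f"{m}_post"], wide["set"]
            )
            if compute_anova_bf:
                anova_bf[m] = inference.anova_bf_approx(
                    wide[f"{m}_pre"], wide[f"{m}_post"], wide["set"],
                    mc_iterations=self.anova_bf_iterations,
                    seed=int(rng.integers(2**31)),
                )

        logger.info("mean-ratings tests")
        mean_ratings = inference.mean_ratings_tests(table, rscale=self.rscale)
        group_curves = roc.group_roc(table)

        return PrePostSDTResults(
            model=self,
            sdt=sdt,
            scores=wide.reset_index(),
            overall_tests=overall,
            per_set_tests=per_set,
            anovas=anovas,
            anova_bf=anova_bf,
            mean_ratings=mean_ratings,
            group_roc=group_curves,
            seed=seed,
        )


@dataclass
class PrePostSDTResults:
    """Fitted results of :class:`PrePostSDT` (tables, tests, ANOVAs, exports)."""

    model: PrePostSDT
    sdt: pd.DataFrame
    scores: pd.DataFrame
    overall_tests: dict[str, inference.TestResult]
    per_set_tests: dict[tuple[str, str], inference.TestResult]
    anovas: dict[str, inference.AnovaResult]
    anova_bf: dict[str, pd.DataFrame]
    mean_ratings: dict[str, inference.TestResult]
    group_roc: pd.DataFrame
    seed: int = 0
    extra_manifest: dict[str, Any] = field(default_factory=dict)

    MEASURE_NAMES = {"auc": "Discrimination (AUC)", "bias": 'Response bias (B"D)'}

    # -- tabular views ---------------------------------------------------------

    def contrasts_frame(self) -> pd.DataFrame:
        rows = []
        for m, res in self.overall_tests.items():
            rows.append({"measure": m, "subset": "all", **res.to_dict()})
        for (m, s), res in self.per_set_tests.items():
            rows.append({"measure": m, "subset": f"set_{s}", **res.to_dict()})
        for cat, res in self.mean_ratings.items():
            rows.append({"measure": "mean_rating", "subset": cat, **res.to_dict()})
        return pd.DataFrame(rows)

    def anova_frame(self) -> pd.DataFrame:
        frames = []
        for m, res in self.anovas.items():
            t = res.table.copy()
            t.insert(0, "measure", m)
            if m in self.anova_bf:
                t["bf10_approx"] = self.anova_bf[m]["bf10"]
                t["bf_se"] = self.anova_bf[m]["bf_se"]
            frames.append(t.reset_index())
        return pd.concat(frames, ignore_index=True)

    def phase_descriptives(self) -> pd.DataFrame:
        return (
            self.sdt.groupby("phase", observed=True)[["auc", "bias"]]
            .agg(["mean", "std"])
            .round(4)
        )

    # -- reporting -------------------------------------------------------------

    def summary(self) -> str:
        lines = []
        n = self.sdt["participant_id"].nunique()
        set_sizes = (
            self.scores.groupby("set")["participant_id"].nunique().to_dict()
        )
        lines.append("Pre/post signal-detection (ROC) analysis")
        lines.append("=" * 72)
        lines.append(
            f"Participants: {n}  "
            + "  ".join(f"set {s}: {c}" for s, c in sorted(set_sizes.items()))
        )
        desc = self.sdt.groupby("phase", observed=True)[["auc", "bias"]].agg(["mean", "std"])
        for m in ("auc", "bias"):
            lines.append("")
            lines.append(self.MEASURE_NAMES[m])
            lines.append("-" * 72)
            for phase in ("pre", "post"):
                mu = desc.loc[phase, (m, "mean")]
                sd = desc.loc[phase, (m, "std")]
                lines.append(f"  {phase:<5} M = {mu: .3f}  SD = {sd:.3f}")
            res = self.overall_tests[m]
            lines.append(
                f"  paired t({res.df}) = {res.t:.2f}, p = {res.p:.3f}, "
                f"dz = {res.dz:.2f}, BF10 = {res.bf10:.2f}"
            )
            for s in ("A", "B"):
                if (m, s) in self.per_set_tests:
                    r = self.per_set_tests[(m, s)]
                    lines.append(
                        f"    set {s}: t({r.df}) = {r.t:.2f}, p = {r.p:.3f}, "
                        f"dz = {r.dz:.2f}, BF10 = {r.bf10:.2f}"
                    )
            lines.append(f"  mixed ANOVA (test x condition):")
            tab = self.anovas[m].table
            for effect in tab.index:
                row = tab.loc[effect]
                extra = ""
                if m in self.anova_bf:
                    bf = self.anova_bf[m].loc[effect]
                    extra = f", BF10 ~= {bf['bf10']:.2f} (MC se {bf['bf_se']:.2f})"
                lines.append(
                    f"    {effect:<12} F(1, {int(row['df2'])}) = {row['F']:.2f}, "
                    f"p = {row['p']:.3f}, ges = {row['ges']:.4f}{extra}"
                )
        lines.append("")
        lines.append("Mean reliability ratings (pre vs post, per category)")
        lines.append("-" * 72)
        for cat, res in self.mean_ratings.items():
            lines.append(
                f"  {cat:<14} t({res.df}) = {res.t:.2f}, p = {res.p:.3f}, "
                f"dz = {res.dz:.2f}, BF10 = {res.bf10:.2f}"
            )
        return "\n".join(lines)

    def manifest(self) -> dict:
        model = self.model
        return {
            "newssdt_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": self.seed,
            "rscale": model.rscale,
            "anova_bf_iterations": model.anova_bf_iterations,
            "criterion_set_policy": "k = scale_max..2 (k=1 excluded)",
            "bdprime_corner_convention": "B\"D := 0 at (HR,FAR) in {(1,0),(0,1)}",
            "scale_max": model.table.scale_max,
            "n_participants": model.table.n_participants,
            "config_hash": io_model.config_digest(
                {
                    "rscale": model.rscale,
                    "anova_bf_iterations": model.anova_bf_iterations,
                    "seed": self.seed,
                    "scale_max": model.table.scale_max,
                    "participants": model.table.participants,
                }
            ),
            **self.extra_manifest,
        }

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write the report bundle (TSV/JSON) and manifest; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def tsv(name: str, df: pd.DataFrame) -> None:
            p = outdir / name
            df.to_csv(p, sep="\t", index=False, float_format="%.10g")
            paths[name] = p

        tsv("sdt_summary.tsv", self.sdt)
        tsv("contrasts.tsv", self.contrasts_frame())
        tsv("anova.tsv", self.anova_frame())
        tsv("group_roc.tsv", self.group_roc)
        results_json = {
            "overall": {m: r.to_dict() for m, r in self.overall_tests.items()},
            "per_set": {f"{m}_set{s}": r.to_dict() for (m, s), r in self.per_set_tests.items()},
            "anova": {
                m: json.loads(self.anovas[m].table.to_json(orient="index"))
                for m in self.anovas
            },
            "anova_bf": {
                m: json.loads(df.to_json(orient="index")) for m, df in self.anova_bf.items()
            },
            "mean_ratings": {c: r.to_dict() for c, r in self.mean_ratings.items()},
        }
        (outdir / "results.json").write_text(json.dumps(results_json, indent=2))
        paths["results.json"] = outdir / "results.json"
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))
        paths["manifest.json"] = outdir / "manifest.json"
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        paths["summary.txt"] = outdir / "summary.txt"
        return paths


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end pipeline configuration (paths resolved at run start)."""

    input_path: Path
    output_dir: Path
    scale_max: int = 7
    flags_path: Path | None = None
    rscale: float = inference.DEFAULT_RSCALE
    anova_bf_iterations: int = 10_000
    seed: int = 0
    compute_anova_bf: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_path", Path(self.input_path))
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        if self.flags_path is not None:
            object.__setattr__(self, "flags_path", Path(self.flags_path))


def run_full_analysis(config: AnalysisConfig) -> PrePostSDTResults:
    """Read -> screen -> summarise -> infer -> write the report bundle."""
    logger.info("reading %s", config.input_path)
    table = io_model.read_ratings_csv(config.input_path, scale_max=config.scale_max)
    flags = io_model.read_flags_tsv(config.flags_path) if config.flags_path else None
    table, exclusions = io_model.apply_exclusions(table, flags=flags)
    logger.info("excluded %d participant(s)", len(exclusions.excluded_ids))
    model = PrePostSDT(
        table, rscale=config.rscale, anova_bf_iterations=config.anova_bf_iterations
    )
    results = model.fit(seed=config.seed, compute_anova_bf=config.compute_anova_bf)
    results.extra_manifest.update(
        {
            "input_path": str(config.input_path),
            "n_excluded": len(exclusions.excluded_ids),
            "exclusion_threshold_seconds": exclusions.threshold_seconds,
        }
    )
    paths = results.save(config.output_dir)
    exclusions.to_tsv(config.output_dir / "exclusions.tsv")
    paths["exclusions.tsv"] = config.output_dir / "exclusions.tsv"
    logger.info("wrote %d report files to %s", len(paths), config.output_dir)
    return results
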