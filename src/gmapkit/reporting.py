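"""Run configuration, cross-readout comparison, and the end-to-end driver.

The comparison report correlates per-barcode sequencing read counts with
array signal over the shared barcode universe, before and after the
detection filters (minimum read count, array log2 signal threshold).  The
end-to-end driver runs simulate -> count/deconvolve -> report from a single
hierarchical config and stamps every output with (tool version, run_id,
seed, config hash) so identical configs reproduce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

import gmapkit
from gmapkit import arrays as arr
from gmapkit import seqreads as seqr
from gmapkit import simulate as sim
from gmapkit.manifest import ProbeClassSpec, build_manifest, gcbg_class_spec

__all__ = [
    "RunConfig",
    "correlate",
    "compare_readouts",
    "run_end_to_end",
    "normalize_replicate_arrays",
    "write_table",
]


def _config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Validated end-to-end run configuration."""

    params: dict
    run_id: str
    seed: int

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        params = dict(raw)
        if "run_id" not in params:
            raise ValueError("config key 'run_id' is required")
        if "seed" not in params:
            raise ValueError("config key 'seed' is required")
        for key in ("library_path", "annotation_path"):
            if key in params and params[key] is not None:
                if not Path(params[key]).exists():
                    raise ValueError(f"config key {key!r}: path does not exist")
        return cls(params=params, run_id=str(params["run_id"]), seed=int(params["seed"]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        return _config_hash(self.params)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    run_id: str = "adhoc",
    seed: int | None = None,
    config_hash: str = "-",
    index: bool = False,
) -> None:
    """Write a TSV with the standard metadata comment header."""
    header = (
        f"# gmapkit {gmapkit.__version__}\n"
        f"# run_id: {run_id}\n"
        f"# seed: {seed}\n"
        f"# config_hash: {config_hash}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def correlate(
    x: pd.Series, y: pd.Series, method: str = "spearman"
) -> tuple[float, int]:
    """Correlation over the shared-barcode intersection.

    Pairs with missing values are dropped.  Returns ``(coefficient, n_pairs)``.
    Spearman uses average ranks for ties.
    """
    shared = x.index.intersection(y.index)
    xv = x.loc[shared].astype(float)
    yv = y.loc[shared].astype(float)
    ok = xv.notna() & yv.notna()
    xv, yv = xv[ok], yv[ok]
    if len(xv) < 3:
        raise ValueError(f"need >= 3 shared barcodes, got {len(xv)}")
    if method == "spearman":
        coef = stats.spearmanr(xv, yv).statistic
    elif method == "pearson":
        coef = stats.pearsonr(xv, yv).statistic
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(coef), int(len(xv))


def compare_readouts(
    count_table: pd.Series,
    array_signal_table: pd.Series,
    min_reads: int = 16,
    threshold: float = 7.89,
    method: str = "spearman",
) -> dict:
    """Correlate sequencing counts against array signal, raw and filtered.

    The filtered correlation drops barcodes with fewer than ``min_reads``
    reads or array log2 signal below ``threshold``.  Returns a report dict;
    when the post-filter set is empty the report carries ``empty=True`` and
    no filtered coefficient.
    """
    shared = count_table.index.intersection(array_signal_table.index)
    report: dict = {
        "n_shared": int(len(shared)),
        "min_reads": min_reads,
        "threshold": threshold,
        "method": method,
        "empty": False,
    }
    if len(shared) < 3:
        report["empty"] = True
        return report
    counts = count_table.loc[shared]
    signal = array_signal_table.loc[shared]
    report["correlation"], _ = correlate(counts, signal, method)
    keep = (counts >= min_reads) & (signal >= threshold)
    report["n_filtered"] = int(keep.sum())
    if keep.sum() < 3:
        report["empty"] = True
        return report
    report["filtered_correlation"], _ = correlate(counts[keep], signal[keep], method)
    return report


_E2E_DEFAULTS = {
    "n_barcodes": 5000,
    "n_duplicated": 10,
    "sample_design": "mix_2_5_10_20",
    "reference_design": "even_78k",
    "total_reads": 200_000,
    "error_rate": 0.001,
    "min_reads": 16,
    "z": 1.96,
    "n_gcbg": 2000,
    "n_replicate_arrays": 2,
    "amplitude": 30000.0,
    "half_saturation": 1.0,
    "background": 120.0,
    "noise_sd": 0.25,
}


def normalize_replicate_arrays(
    feature_tables: list[pd.DataFrame], span: float = 0.4
) -> pd.Series:
    """Within-condition array processing: GCbg-correct each replicate array,
    summarize replicate features per barcode, cyclic-loess normalize across
    the replicate arrays, and average the normalized log2 signals.

    Cyclic loess assumes most barcodes are unchanged between the arrays it
    normalizes, which holds for replicate hybridizations of one sample but
    not for sample-vs-reference pairs with diluted subpools; ratios between
    conditions are therefore taken only after within-condition normalization.
    """
    signals = {
        f"rep{i}": arr.summarize_replicates(arr.gcbg_correct(t))
        for i, t in enumerate(feature_tables)
    }
    if len(signals) == 1:
        only = next(iter(signals.values()))
        return pd.Series(np.log2(only.to_numpy()), index=only.index)
    norm = arr.cyclic_loess_normalize(signals, span=span)
    return pd.concat(norm.values(), axis=1).mean(axis=1)

#: Artifact filenames emitted by :func:`run_end_to_end`.
E2E_ARTIFACTS = (
    "pool_design.tsv",
    "seq_counts.tsv",
    "seq_ratios.tsv",
    "array_ratios.tsv",
    "subpool_summary.tsv",
    "compare_report.tsv",
)


def run_end_to_end(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a dilution experiment and push it through both read-outs.

    Stages: simulate (library, designs, reads, array) -> count/deconvolve
    (matcher counts; GCbg-correct, replicate median, loess, ratios) ->
    report (subpool summaries, cross-readout comparison).  Any stage failure
    removes partial outputs and re-raises with the stage name.
    """
    p = dict(_E2E_DEFAULTS)
    p.update({k: v for k, v in config.params.items() if k in _E2E_DEFAULTS})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(run_id=config.run_id, seed=config.seed, config_hash=config.config_hash)
    written: list[Path] = []
    stage = "simulate"
    try:
        seed = config.seed
        library = sim.make_library(p["n_barcodes"], p["n_duplicated"], seed=seed)
        sample_design = sim.make_pool_design(library, p["sample_design"], seed=seed + 1)
        ref_design = sim.make_pool_design(library, p["reference_design"], seed=seed + 1)

        # sequencing read-out
        ref_reads, _ = sim.simulate_reads(
            ref_design.concentrations, library, p["total_reads"],
            p["error_rate"], seed=seed + 2,
        )
        smp_reads, _ = sim.simulate_reads(
            sample_design.concentrations, library, p["total_reads"],
            p["error_rate"], seed=seed + 3,
        )

        # array read-out: barcode features + GC-background probes
        hp_spec = ProbeClassSpec("HP", "shRNA barcode features", len(library), 3, 22)
        manifest = build_manifest(
            [hp_spec, gcbg_class_spec(p["n_gcbg"])], library=library, seed=seed + 4
        )
        n_rep = int(p["n_replicate_arrays"])
        ref_feats = [
            sim.simulate_array_signal(
                ref_design.concentrations,
                sim.ArraySignalModel(
                    p["amplitude"], p["half_saturation"], p["background"],
                    p["noise_sd"], seed=seed + 10 + k,
                ),
                manifest,
                f"reference_rep{k}",
            )
            for k in range(n_rep)
        ]
        smp_feats = [
            sim.simulate_array_signal(
                sample_design.concentrations,
                sim.ArraySignalModel(
                    p["amplitude"], p["half_saturation"], p["background"],
                    p["noise_sd"], seed=seed + 20 + k,
                ),
                manifest,
                f"sample_rep{k}",
            )
            for k in range(n_rep)
        ]

        stage = "deconvolve"
        counts_ref, _ = seqr.count_reads(ref_reads, library)
        counts_smp, _ = seqr.count_reads(smp_reads, library)
        log2_ref, _ = seqr.log2_counts(counts_ref, p["min_reads"])
        log2_smp, _ = seqr.log2_counts(counts_smp, p["min_reads"])
        bulk_label = (
            sim.BUILTIN_DESIGNS[p["sample_design"]].bulk_label
            if isinstance(p["sample_design"], str)
            else "median"
        )
        seq_ratios = arr.log2_ratios(
            log2_smp, log2_ref, sample_design.subpool_labels,
            "sample_seq", "reference_seq", center=bulk_label,
        )

        sig_ref = normalize_replicate_arrays(ref_feats)
        sig_smp = normalize_replicate_arrays(smp_feats)
        array_ratios = arr.log2_ratios(
            sig_smp, sig_ref, sample_design.subpool_labels,
            "sample_array", "reference_array",
        )

        stage = "report"
        seq_summary = arr.subpool_distribution(seq_ratios)
        array_summary = arr.subpool_distribution(array_ratios)
        seq_summary["readout"] = "sequencing"
        array_summary["readout"] = "array"
        summary = pd.concat([seq_summary, array_summary])
        report = compare_readouts(
            counts_smp, sig_smp, p["min_reads"],
            threshold=float(sig_ref.median()) - 2.0,
        )

        def _emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
            path = outdir / name
            write_table(df, path, index=index, **meta)
            written.append(path)

        _emit("pool_design.tsv", sample_design.to_frame())
        _emit("seq_counts.tsv", counts_smp.rename("count").rename_axis("barcode_id").reset_index())
        _emit("seq_ratios.tsv", seq_ratios.ratios)
        _emit("array_ratios.tsv", array_ratios.ratios)
        _emit("subpool_summary.tsv", summary, index=True)
        _emit("compare_report.tsv", pd.DataFrame([report]))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"end-to-end run failed at stage {stage!r}: {exc}") from exc
    return {path.name: path for path in written}
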