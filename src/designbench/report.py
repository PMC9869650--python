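"""Per-model evaluation reports and cross-model comparisons.

``build_model_report`` glues the pipeline together: read structures via
the dataset map, canonicalize residues, align prediction rows by order,
assign secondary structure (built-in assigner or imported DSSP files),
then compute every metric group.  ``compare_models`` tabulates one
metric across models per fold class; ``render_plots`` emits the four
standard panels (prediction-bias bars, accuracy-vs-resolution scatter,
confusion heat map, per-fold-class comparison bars), each with a CSV
twin carrying the exact plotted numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import secstruct
from .geometry import phi_psi, ramachandran_comparison
from .io_formats import (ALPHABET, BackboneStructure, DatasetMap,
                         PredictionSet, UNKNOWN_AA, ValidationError,
                         read_dssp_file, read_pdb_backbone)
from .metrics import (ConfusionMatrix, GroupMetrics, ScoredResidue,
                      argmax_labels, build_confusion, group_metrics,
                      per_class_metrics, resolution_correlation,
                      stratified_metrics)

logger = logging.getLogger(__name__)


@dataclass
class ModelReport:
    model_name: str
    scored: list[ScoredResidue]
    per_class: pd.DataFrame
    global_metrics: GroupMetrics
    by_chain: dict[str, GroupMetrics]
    by_ss: dict[str, GroupMetrics]
    by_fold_class: dict[str, GroupMetrics]
    by_architecture: dict[str, GroupMetrics]
    confusion: ConfusionMatrix
    resolution_r: float | None
    exclusions: dict[str, int]
    chain_resolutions: dict[str, float | None] = field(default_factory=dict)

    @property
    def residue_signature(self) -> tuple:
        """Identity of the evaluated residue set, for comparisons."""
        return tuple(sorted(
            (c, "".join(r.aa_true for r in g))
            for c, g in _group_by_chain(self.scored).items()))


def _group_by_chain(scored: list[ScoredResidue]) -> dict[str, list[ScoredResidue]]:
    out: dict[str, list[ScoredResidue]] = {}
    for r in scored:
        out.setdefault(r.chain_key, []).append(r)
    return out


def load_structures(dmap: DatasetMap,
                    base_dir: str | Path = ".") -> dict[str, BackboneStructure]:
    """Load every chain listed in a dataset map.

    Relative structure paths are resolved against ``base_dir`` (normally
    the directory containing the map file).
    """
    base = Path(base_dir)
    out = {}
    for entry in dmap:
        path = Path(entry.structure_path)
        if not path.is_absolute():
            path = base / path
        chain_id = entry.chain_key.rsplit("_", 1)[-1]
        st = read_pdb_backbone(path, chain_id)
        st.chain_key = entry.chain_key
        out[entry.chain_key] = st
    return out


def _chain_ss_labels(structure: BackboneStructure, ss_source: str,
                     dssp_dir: str | Path | None) -> list[secstruct.SSLabel]:
    if ss_source == "builtin":
        return secstruct.assign_secondary_structure(structure)
    if ss_source == "dssp-dir":
        if dssp_dir is None:
            raise ValueError("ss_source='dssp-dir' requires dssp_dir")
        pdb_id = structure.chain_key.rsplit("_", 1)[0]
        path = Path(dssp_dir) / f"{pdb_id}.dssp"
        return secstruct.labels_from_dssp(read_dssp_file(path), structure)
    raise ValueError(f"unknown ss_source {ss_source!r}")


def build_model_report(preds: PredictionSet,
                       structures: dict[str, BackboneStructure],
                       dmap: DatasetMap,
                       ss_source: str = "builtin",
                       dssp_dir: str | Path | None = None) -> ModelReport:
    """Align one model's predictions with the structures and compute the
    full metric report.

    Prediction rows align to canonicalized residues by order; residues
    whose identity could not be canonicalized carry no ground truth, are
    excluded from scoring and counted per chain in ``exclusions``.  A
    row-count mismatch is a hard error, never silently truncated.
    """
    by_key = dmap.by_chain()
    missing = [c for c in preds.chain_keys if c not in by_key]
    if missing:
        raise ValidationError(
            f"chains in predictions absent from dataset map: {missing}")

    scored: list[ScoredResidue] = []
    exclusions: dict[str, int] = {}
    chain_resolutions: dict[str, float | None] = {}
    for chain_key in preds.chain_keys:
        entry = by_key[chain_key]
        structure = structures[chain_key]
        labels = _chain_ss_labels(structure, ss_source, dssp_dir)
        known = [(r, lab) for r, lab in zip(structure.residues, labels)
                 if r.aa_true != UNKNOWN_AA]
        exclusions[chain_key] = len(structure.residues) - len(known)
        mat = preds.rows[chain_key]
        if len(mat) != len(known):
            raise ValidationError(
                f"chain {chain_key}: {len(mat)} prediction rows but "
                f"{len(known)} scoreable residues")
        chain_resolutions[chain_key] = structure.resolution
        for (res, lab), probs in zip(known, mat):
            scored.append(ScoredResidue(
                chain_key=chain_key, aa_true=res.aa_true, probs=probs,
                ss=lab.state, fold_class=entry.fold_class,
                architecture_code=entry.architecture_code,
                resolution=structure.resolution))

    cm = build_confusion(scored)
    by_chain = stratified_metrics(scored, lambda r: r.chain_key)
    per_chain_pts = [(by_chain[c].accuracy, chain_resolutions[c])
                     for c in by_chain]
    report = ModelReport(
        model_name=preds.model_name,
        scored=scored,
        per_class=per_class_metrics(scored, cm),
        global_metrics=group_metrics(scored),
        by_chain=by_chain,
        by_ss=stratified_metrics(scored, lambda r: r.ss),
        by_fold_class=stratified_metrics(scored, lambda r: r.fold_class),
        by_architecture=stratified_metrics(scored,
                                           lambda r: r.architecture_code),
        confusion=cm,
        resolution_r=resolution_correlation(per_chain_pts),
        exclusions=exclusions,
        chain_resolutions=chain_resolutions,
    )
    logger.info("model %s: %d residues scored, accuracy %.3f",
                preds.model_name, len(scored),
                report.global_metrics.accuracy)
    return report


# ---------------------------------------------------------------------------
# Cross-model comparison
# ---------------------------------------------------------------------------

COMPARISON_METRICS = ("accuracy", "macro_recall", "similarity",
                      "macro_precision", "top3")


def compare_models(reports: list[ModelReport],
                   metric: str = "accuracy") -> pd.DataFrame:
    """One metric per model per fold class (plus global).

    All reports must cover the identical residue set — same chains, same
    native sequences; a silent intersection would make the bars
    incomparable, so a mismatch is an error.  Row order follows input
    order.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 reports to compare")
    if metric not in COMPARISON_METRICS:
        raise ValueError(f"unknown comparison metric {metric!r}")
    sig = reports[0].residue_signature
    for rep in reports[1:]:
        if rep.residue_signature != sig:
            raise ValidationError(
                f"model {rep.model_name!r} was evaluated on a different "
                f"residue set than {reports[0].model_name!r}")
    strata = sorted({s for rep in reports for s in rep.by_fold_class})
    rows = []
    for rep in reports:
        row = {"model": rep.model_name,
               "global": getattr(rep.global_metrics, metric)}
        for s in strata:
            gm = rep.by_fold_class.get(s)
            row[s] = getattr(gm, metric) if gm else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


# ---------------------------------------------------------------------------
# Tabular and graphical output
# ---------------------------------------------------------------------------

def _metrics_frame(groups: dict[str, GroupMetrics], key_name: str
                   ) -> pd.DataFrame:
    rows = []
    for key, gm in groups.items():
        rows.append({key_name: key, "accuracy": gm.accuracy,
                     "macro_precision": gm.macro_precision,
                     "macro_recall": gm.macro_recall,
                     "similarity": gm.similarity, "top3": gm.top3,
                     "n_residues": gm.n_residues})
    return pd.DataFrame(rows)


def composition_frame(dmap: DatasetMap) -> pd.DataFrame:
    """Chain counts per fold class for a dataset map."""
    counts: dict[str, int] = {}
    for e in dmap:
        counts[e.fold_class] = counts.get(e.fold_class, 0) + 1
    return pd.DataFrame(sorted(counts.items()),
                        columns=["fold_class", "n_chains"])


def write_report_csvs(report: ModelReport, out_dir: str | Path,
                      dmap: DatasetMap | None = None) -> None:
    """Write the tidy per-group metric tables for one model."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pc = report.per_class.copy()
    pc.insert(0, "aa", pc.index)
    pc.to_csv(out / "per_class.csv", index=False)
    _metrics_frame(report.by_chain, "chain_key").to_csv(
        out / "per_chain.csv", index=False)
    _metrics_frame(report.by_ss, "ss").to_csv(out / "per_ss.csv", index=False)
    _metrics_frame(report.by_architecture, "architecture_code").to_csv(
        out / "per_architecture.csv", index=False)
    _metrics_frame(report.by_fold_class, "fold_class").to_csv(
        out / "per_fold_class.csv", index=False)
    report.confusion.to_frame().to_csv(out / "confusion_matrix.csv",
                                       index_label="true_aa")
    pd.DataFrame(
        [{"chain_key": c, "excluded_residues": n}
         for c, n in sorted(report.exclusions.items())]
    ).to_csv(out / "exclusions.csv", index=False)
    if dmap is not None:
        composition_frame(dmap).to_csv(out / "composition.csv", index=False)


def write_ramachandran_csv(report: ModelReport,
                           structures: dict[str, BackboneStructure],
                           out_dir: str | Path) -> None:
    """Pooled true-vs-predicted torsion histograms, long-format CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_chain = _group_by_chain(report.scored)
    frames = []
    for chain_key, group in by_chain.items():
        structure = structures[chain_key]
        known = [r for r in structure.residues if r.aa_true != UNKNOWN_AA]
        torsion_all = phi_psi(structure)
        keep = [t for r, t in zip(structure.residues, torsion_all)
                if r.aa_true != UNKNOWN_AA]
        true_seq = "".join(r.aa_true for r in known)
        pred_idx = argmax_labels(group)
        pred_seq = "".join(ALPHABET[i] for i in pred_idx)
        frames.append(ramachandran_comparison(keep, true_seq,
                                              pred_seq).to_frame())
    combined = (pd.concat(frames, ignore_index=True)
                .groupby(["aa", "mode", "phi_bin", "psi_bin"], as_index=False)
                ["count"].sum())
    combined.to_csv(out / "ramachandran_comparison.csv", index=False)


def _use_agg():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def render_plots(report: ModelReport, out_dir: str | Path,
                 dmap: DatasetMap | None = None) -> list[Path]:
    """Render the standard per-model panels; every plot gets a CSV twin.

    * bias-vs-abundance bars (per amino acid),
    * accuracy-vs-resolution scatter with the Pearson r (skipped with a
      logged notice when the correlation is undefined),
    * 20x20 confusion heat map.
    """
    plt = _use_agg()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # (A) prediction bias vs abundance
    counts = report.confusion.counts
    abundance = counts.sum(axis=1) / counts.sum()
    bias_df = pd.DataFrame({"aa": list(ALPHABET),
                            "abundance": abundance,
                            "bias": report.per_class["bias"].to_numpy()})
    bias_df.to_csv(out / "bias_abundance.csv", index=False)
    order = np.argsort(-abundance, kind="stable")
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(np.array(list(ALPHABET))[order], bias_df["bias"].to_numpy()[order])
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("amino acid (by decreasing abundance)")
    ax.set_ylabel("prediction bias")
    ax.set_title(f"{report.model_name}: prediction bias")
    fig.savefig(out / "bias_abundance.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    written += [out / "bias_abundance.csv", out / "bias_abundance.png"]

    # (B) accuracy vs resolution
    res_df = pd.DataFrame(
        [{"chain_key": c, "accuracy": report.by_chain[c].accuracy,
          "resolution": report.chain_resolutions.get(c)}
         for c in report.by_chain])
    res_df.to_csv(out / "accuracy_vs_resolution.csv", index=False)
    written.append(out / "accuracy_vs_resolution.csv")
    if report.resolution_r is None:
        logger.info("model %s: resolution correlation undefined, "
                    "scatter plot skipped", report.model_name)
    else:
        usable = res_df.dropna(subset=["resolution"])
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(usable["resolution"], usable["accuracy"], s=18)
        ax.set_xlabel("resolution (A)")
        ax.set_ylabel("chain accuracy")
        ax.set_title(f"{report.model_name}: r = {report.resolution_r:.3f}")
        fig.savefig(out / "accuracy_vs_resolution.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)
        written.append(out / "accuracy_vs_resolution.png")

    # (C) confusion heat map
    long = (report.confusion.to_frame()
            .stack().rename("count").reset_index())
    long.columns = ["true_aa", "predicted_aa", "count"]
    long.to_csv(out / "confusion_long.csv", index=False)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(report.confusion.counts, cmap="viridis")
    ax.set_xticks(range(20), list(ALPHABET))
    ax.set_yticks(range(20), list(ALPHABET))
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, label="count")
    ax.set_title(f"{report.model_name}: confusion")
    fig.savefig(out / "confusion.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    written += [out / "confusion_long.csv", out / "confusion.png"]

    if dmap is not None:
        composition_frame(dmap).to_csv(out / "composition.csv", index=False)
        written.append(out / "composition.csv")
    return written


def render_comparison_plot(table: pd.DataFrame, out_dir: str | Path,
                           metric: str = "accuracy") -> list[Path]:
    """Grouped per-fold-class comparison bars (plus global), CSV twin in
    long format (model, stratum, value): k models x (classes + global)
    rows."""
    plt = _use_agg()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long = (table.reset_index()
            .melt(id_vars="model", var_name="stratum", value_name=metric))
    long.to_csv(out / "comparison.csv", index=False)
    strata = list(table.columns)
    x = np.arange(len(strata))
    width = 0.8 / len(table)
    fig, ax = plt.subplots(figsize=(1.8 * len(strata) + 2, 4))
    for k, (model, row) in enumerate(table.iterrows()):
        ax.bar(x + k * width, row.to_numpy(dtype=float), width, label=model)
    ax.set_xticks(x + 0.4 - width / 2, strata)
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    fig.savefig(out / "comparison.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    return [out / "comparison.csv", out / "comparison.png"]
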