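"""End-to-end pipeline: dataset -> thermodynamics -> structures ->
features -> statistics, with reproducible, checksummed outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import dataset as ds
from . import geometry as geo
from . import stats as st
from . import thermo as th
from .dataset import DuplexPair, classify_activity, load_table1, loss_category
from .ensemble import SynthSpec
from .structure import build_duplex, synthesize_ensemble

logger = logging.getLogger("sirnakit")

__all__ = ["RunConfig", "run_pipeline", "report_render"]


@dataclass
class RunConfig:
    """Pipeline configuration; fully serialized into every run's output."""

    seed: int = 0
    table_path: str | None = None  # None -> packaged duplex table
    output_dir: str | None = None
    with_structures: bool = True  # build 3D duplexes and compute SASA/V
    with_ensembles: bool = False  # small synthetic ensembles per duplex
    n_frames: int = 50
    noise_sigma: float = 0.1  # A, independent per-atom thermal jitter
    fray_prob: float = 0.1
    pucker_occupancy: float = 0.05  # baseline C2'-endo occupancy
    positional_convention: str = "flank-average"

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _activity_section(pairs: list[DuplexPair]) -> dict:
    labels = {p.pair_id: classify_activity(p) for p in pairs}
    cats = {p.pair_id: loss_category(p) for p in pairs}
    dtm = {p.pair_id: p.delta_tm for p in pairs}
    return {
        "n_pairs": len(pairs),
        "n_by_target": {
            t: sum(p.parent.target == t for p in pairs)
            for t in sorted({p.parent.target for p in pairs})
        },
        "n_active": sum(v.label == "active" for v in labels.values()),
        "n_inactive": sum(v.label == "inactive" for v in labels.values()),
        "n_censored": sum(c == "censored" for c in cats.values()),
        "n_moderate_loss": sum(c == "moderate" for c in cats.values()),
        "n_unaffected": sum(c == "unaffected" for c in cats.values()),
        "labels": {k: v.label for k, v in labels.items()},
        "fold_change": {
            k: (v.fold_change if v.fold_change is not None else None)
            for k, v in labels.items()
        },
        "delta_tm": dtm,
        "delta_tm_min": min(dtm.values()),
        "delta_tm_mean": float(np.mean(list(dtm.values()))),
    }


def _thermo_section(pairs: list[DuplexPair], convention: str) -> dict:
    results = {}
    for p in pairs:
        for rec in (p.parent, p.modified):
            t = th.duplex_thermo(rec, convention=convention)
            results[rec.duplex_id] = t
    meas = [p.parent.tm_C for p in pairs]
    pred = [results[p.parent.duplex_id].tm_pred for p in pairs]
    r_tm = st.pearson_with_p(pred, meas, subset="parent")
    dg = [results[p.parent.duplex_id].dG37 for p in pairs]
    r_dg = st.pearson_with_p(dg, meas, subset="parent")
    # positional dE2 contrast over modified duplexes
    labels = np.array([classify_activity(p).label for p in pairs])
    de_mat = np.stack(
        [results[p.modified.duplex_id].positional_dE[:19] for p in pairs]
    )
    contrast = st.group_contrast(de_mat, labels)
    de2 = de_mat[:, 1]
    svm_pts = []
    svm_labels = []
    for j in range(8):  # seed region positions g1..g8
        for i, p in enumerate(pairs):
            svm_pts.append([j + 1, de_mat[i, j]])
            svm_labels.append(labels[i])
    svm = st.linear_svm_separator(np.array(svm_pts), np.array(svm_labels))
    return {
        "results": results,
        "tm_pred_vs_measured_parents": r_tm,
        "dG37_vs_measured_tm_parents": r_dg,
        "dE2_mean_active": float(de2[labels == "active"].mean()),
        "dE2_mean_inactive": float(de2[labels == "inactive"].mean()),
        "positional_contrast": contrast,
        "svm_seed_region": {k: v for k, v in svm.items() if k != "predict"},
    }


def _structure_section(pairs: list[DuplexPair], cfg: RunConfig) -> dict:
    feats: dict[str, dict] = {}
    for p in pairs:
        for rec in (p.parent, p.modified):
            logger.info("building %s", rec.duplex_id)
            built = build_duplex(rec)
            top, xyz = built.topology, built.coords
            total, per_atom = geo.sasa(top, xyz)
            V, rho = geo.volume_density(top, xyz)
            row = {
                "SASA": total,
                "SASA_seed_guide": geo.region_sasa(top, per_atom, "guide", range(1, 9)),
                "V": V,
                "rho": rho,
                "X": geo.end_to_end(top, xyz),
                "NBP": geo.count_base_pairs(top, xyz),
                "NBS": geo.count_base_stacks(top, xyz),
            }
            if cfg.with_ensembles:
                spec = SynthSpec(
                    pucker_occupancy=cfg.pucker_occupancy,
                    positional_noise_sigma=cfg.noise_sigma,
                    fray_prob=cfg.fray_prob,
                    n_frames=cfg.n_frames,
                    seed=cfg.seed,
                )
                ens = synthesize_ensemble(built, spec)
                nbp = [geo.count_base_pairs(top, ens.frames[f]) for f in range(ens.n_frames)]
                row["NBP_mean"] = float(np.mean(nbp))
                row["NBP_min"], row["NBP_max"] = int(min(nbp)), int(max(nbp))
            feats[rec.duplex_id] = row
    ordering = {
        "sasa_mod_gt_parent": sum(
            feats[p.modified.duplex_id]["SASA"] > feats[p.parent.duplex_id]["SASA"]
            for p in pairs
        ),
        "volume_mod_gt_parent": sum(
            feats[p.modified.duplex_id]["V"] > feats[p.parent.duplex_id]["V"]
            for p in pairs
        ),
    }
    return {"features": feats, "ordering": ordering}


def _statistics_section(
    pairs: list[DuplexPair],
    thermo_sec: dict,
    struct_sec: dict | None,
) -> dict:
    labels = {p.pair_id: classify_activity(p) for p in pairs}
    out: dict = {}
    # ln[IC50] correlations on measurable modified duplexes
    usable = [p for p in pairs if not p.modified.ic50_censored]
    ln_ic50 = np.log([p.modified.ic50_nM for p in usable])
    de2 = np.array(
        [thermo_sec["results"][p.modified.duplex_id].positional_dE[1] for p in usable]
    )
    out["lnIC50_vs_dE2_modified"] = st.pearson_with_p(de2, ln_ic50, subset="modified")
    dg = np.array([thermo_sec["results"][p.modified.duplex_id].dG37 for p in usable])
    out["lnIC50_vs_dG37_modified"] = st.pearson_with_p(dg, ln_ic50, subset="modified")
    out["seed_composition"] = st.seed_composition(pairs)

    if struct_sec is not None:
        feats = struct_sec["features"]
        rel_pot = np.log(
            [p.modified.ic50_nM / p.parent.ic50_nM for p in usable]
        )
        sasa_mod = np.array([feats[p.modified.duplex_id]["SASA"] for p in usable])
        out["rel_potency_vs_SASA_modified"] = st.pearson_with_p(
            sasa_mod, rel_pot, subset="modified"
        )
        # feature ranking for ln[IC50] over modified duplexes
        table: dict[str, list[float]] = {}
        for p in usable:
            t = thermo_sec["results"][p.modified.duplex_id]
            f = feats[p.modified.duplex_id]
            row = {
                "SASA": f["SASA"],
                "SASA_seed_guide": f["SASA_seed_guide"],
                "V": f["V"],
                "rho": f["rho"],
                "X": f["X"],
                "dH_nn": t.dH,
                "dG37_nn": t.dG37,
                "tm_pred_nn": t.tm_pred,
                "dE2_nn": t.positional_dE[1],
                "dE6_nn": t.positional_dE[5],
                "stack_tm_g1g2": list(t.stack_tm.values())[0],
                "stack_tm_g2g3": list(t.stack_tm.values())[1],
            }
            for k, v in row.items():
                table.setdefault(k, []).append(v)
        out["feature_ranking"] = st.feature_ranking(
            {k: np.array(v) for k, v in table.items()}, ln_ic50
        )
    out["n_usable_modified"] = len(usable)
    out["labels"] = {k: v.label for k, v in labels.items()}
    return out


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute every stage and return the report bundle.

    The bundle carries the full configuration, input checksums, the
    activity/Tm summary, the NN thermodynamics and its correlations,
    built-structure features with pairwise orderings, and the
    statistics summary.  Identical config + seed give an identical
    bundle.  A stage failure aborts with the stage name.
    """
    cfg = config or RunConfig()
    from .dataset import TABLE1_SHA256
    from .params import FF_SHA256

    bundle: dict = {
        "config": asdict(cfg),
        "config_checksum": cfg.checksum(),
        "input_checksums": {"table1": TABLE1_SHA256, "forcefield": FF_SHA256},
    }
    stage = "dataset"
    try:
        pairs = load_table1(cfg.table_path)
        bundle["activity"] = _activity_section(pairs)
        stage = "thermo"
        bundle["thermo"] = _thermo_section(pairs, cfg.positional_convention)
        struct_sec = None
        if cfg.with_structures:
            stage = "structures"
            struct_sec = _structure_section(pairs, cfg)
            bundle["structures"] = {
                "ordering": struct_sec["ordering"],
                "features": struct_sec["features"],
            }
        stage = "statistics"
        bundle["statistics"] = _statistics_section(pairs, bundle["thermo"], struct_sec)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if cfg.output_dir:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.txt").write_text(report_render(bundle))
        (outdir / "bundle.json").write_text(_to_json(bundle))
    return bundle


def _to_json(bundle: dict) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items()}
        if hasattr(o, "_asdict"):
            return o._asdict()
        return str(o)

    clean = {k: v for k, v in bundle.items()}
    # ThermoResult objects are bulky; keep scalar fields only
    thermo = clean.get("thermo", {})
    if "results" in thermo:
        thermo = dict(thermo)
        thermo["results"] = {
            k: {
                "dH": t.dH,
                "dS": t.dS,
                "dG37": t.dG37,
                "tm_pred": t.tm_pred,
                "positional_dE": t.positional_dE.tolist(),
            }
            for k, t in thermo["results"].items()
        }
        clean["thermo"] = thermo
    return json.dumps(clean, indent=1, default=default)


def report_render(bundle: dict) -> str:
    """One-page text summary of a report bundle."""
    lines = []
    add = lines.append
    add("siRNA duplex analysis summary")
    add(f"config checksum: {bundle.get('config_checksum', 'n/a')}")
    act = bundle.get("activity")
    if act:
        add("")
        add(
            f"pairs: {act['n_pairs']} "
            + " ".join(f"{k}:{v}" for k, v in act["n_by_target"].items())
        )
        add(
            f"activity: {act['n_active']} active / {act['n_inactive']} inactive "
            f"({act['n_censored']} censored, {act['n_moderate_loss']} moderate loss, "
            f"{act['n_unaffected']} unaffected)"
        )
        add(
            f"delta Tm (modified - parent): min {act['delta_tm_min']:.1f} C, "
            f"mean {act['delta_tm_mean']:.1f} C"
        )
    th_sec = bundle.get("thermo")
    if th_sec:
        r1 = th_sec["tm_pred_vs_measured_parents"]
        r2 = th_sec["dG37_vs_measured_tm_parents"]
        add("")
        add(
            f"NN Tm prediction vs measured (parents): r={r1.r:.3f} p={r1.p:.2g} n={r1.n}"
        )
        add(f"NN dG37 vs measured Tm (parents): r={r2.r:.3f} p={r2.p:.2g} n={r2.n}")
        add(
            f"NN dE2 mean: active {th_sec['dE2_mean_active']:.2f}, "
            f"inactive {th_sec['dE2_mean_inactive']:.2f} kcal/mol"
        )
        top = th_sec["positional_contrast"][0]
        add(
            f"largest positional contrast: g{top['position']} "
            f"(Cohen's d {top['cohen_d']:.2f}, raw p {top['p_raw']:.3g})"
        )
        svm = th_sec["svm_seed_region"]
        add(f"seed-region SVM training accuracy: {svm['accuracy']:.2f}")
    else:
        add("")
        add("thermodynamics: not computed")
    stats_sec = bundle.get("statistics")
    if stats_sec:
        add("")
        for key in ("lnIC50_vs_dE2_modified", "rel_potency_vs_SASA_modified"):
            if key in stats_sec:
                c = stats_sec[key]
                add(f"{key}: r={c.r:.3f} p={c.p:.2g} n={c.n}")
        fr = stats_sec.get("feature_ranking")
        if fr:
            add("top-ranked ln[IC50] predictors: " + ", ".join(fr["ranking"][:5]))
    else:
        add("")
        add("statistics: not computed")
    struct = bundle.get("structures")
    if struct:
        o = struct["ordering"]
        add("")
        add(
            f"built-structure orderings: SASA(mod)>SASA(par) in "
            f"{o['sasa_mod_gt_parent']} pairs; V(mod)>V(par) in "
            f"{o['volume_mod_gt_parent']} pairs"
        )
    return "\n".join(lines) + "\n"
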