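"""End-to-end orchestration: synth/load -> QC -> embed -> estimate -> stats.

A single :class:`PipelineConfig` drives every stage; each stage writes its
artifacts (QC TSV, estimate TSV, stats JSON) into the output directory and
identical config + seed gives an identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from infodyn import bayes, knn, stats
from infodyn.embedding import common_dimension, ragwitz_optimize, tau_from_act, EmbeddingSpec
from infodyn.errors import ParameterError
from infodyn.preproc import (
    Recording,
    act,
    load_recording,
    reject_by_amplitude,
    reject_by_delta,
    znormalize,
)
from infodyn.synth import SynthParams, generate_condition_set

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full analysis run."""

    # input: either paths to recording containers, or synthetic parameters
    input_paths: list = field(default_factory=list)
    synth_params: dict | None = None
    synth_conditions: dict | None = None

    # preprocessing
    delta_threshold: float = 0.30
    apply_delta_rejection: bool = False
    amplitude_z_threshold: float | None = None

    # embedding
    optimize_embedding: bool = False
    d_candidates: tuple = (1, 2, 3)
    tau_act_fractions: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    d: int = 1
    tau: int = 1
    ragwitz_k: int = 4

    # estimation
    backends: tuple = ("knn",)          # subset of {"knn", "nsb"}
    k: int = 4
    u_grid: tuple = tuple(range(1, 21))
    n_inner_bins: int = 10
    nsb_support: float = bayes.DEFAULT_SUPPORT

    # statistics
    n_surrogates: int = 100
    surrogate_epochs: int = 20
    n_perm: int = 1000
    seed: int = 0

    out_dir: str = "results"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=str)


def _load_inputs(config: PipelineConfig) -> list:
    if config.input_paths:
        return [load_recording(p) for p in config.input_paths]
    if config.synth_params is None or config.synth_conditions is None:
        raise ParameterError("config needs input_paths or synth_params + synth_conditions")
    base = SynthParams(**config.synth_params)
    return generate_condition_set(base, config.synth_conditions)


def _qc(rec: Recording, config: PipelineConfig):
    tgt = rec.channel(rec.sites[1])
    qcs = reject_by_delta(tgt, rec.fs, config.delta_threshold)
    rejected = {q.epoch_index for q in qcs if q.rejected} if config.apply_delta_rejection else set()
    if config.amplitude_z_threshold is not None:
        for q in reject_by_amplitude(tgt, config.amplitude_z_threshold):
            if q.rejected:
                rejected.add(q.epoch_index)
                qcs[q.epoch_index].rejected = True
                qcs[q.epoch_index].reason = "artifact"
    keep = [i for i in range(rec.n_epochs) if i not in rejected]
    if len(keep) < 2:
        raise ParameterError(f"{rec.session_id}: fewer than 2 epochs survive QC")
    return rec.select_epochs(keep), qcs


def _optimized_spec(recordings: list, config: PipelineConfig):
    """Common embedding dimension over conditions/sites; per-signal tau kept simple."""
    specs = []
    for rec in recordings:
        for site in rec.sites:
            epochs = znormalize(rec.channel(site))
            try:
                act_samples = act(epochs[0])
            except Exception:
                act_samples = 1
            taus = tau_from_act(act_samples, config.tau_act_fractions)
            d, tau, _ = ragwitz_optimize(
                epochs[: min(4, epochs.shape[0])],
                config.d_candidates,
                taus,
                k=config.ragwitz_k,
            )
            specs.append(EmbeddingSpec(d=d, tau=tau))
    d_common = common_dimension(specs)
    tau_common = int(np.median([s.tau for s in specs]))
    return d_common, max(tau_common, 1)


def _estimate_knn(rec: Recording, d: int, tau: int, config: PipelineConfig) -> list:
    src_site, tgt_site = rec.sites
    records = []
    meta = dict(condition=rec.condition, session_id=rec.session_id)
    norm = {s: znormalize(rec.channel(s)) for s in rec.sites}
    # per-direction optimized transfer delay from pooled epochs
    u_opt = {}
    for direction, (a, b) in {
        f"{src_site}->{tgt_site}": (src_site, tgt_site),
        f"{tgt_site}->{src_site}": (tgt_site, src_site),
    }.items():
        scan = knn.scan_delay(
            norm[a][: min(8, rec.n_epochs)],
            norm[b][: min(8, rec.n_epochs)],
            d_x=d, d_y=d, tau=tau, u_grid=config.u_grid, k=config.k,
        )
        u_opt[direction] = scan.u_opt
    for ep in range(rec.n_epochs):
        for site in rec.sites:
            records.append(
                knn.EstimateRecord(
                    measure="H",
                    value=knn.kl_entropy(norm[site][ep], k=config.k),
                    direction_or_site=site,
                    epoch_index=ep,
                    params={"k": config.k},
                    **meta,
                )
            )
            r = knn.ais(norm[site][ep], d=d, tau=tau, k=config.k, **meta)
            r.direction_or_site = site
            r.epoch_index = ep
            records.append(r)
        for direction, (a, b) in {
            f"{src_site}->{tgt_site}": (src_site, tgt_site),
            f"{tgt_site}->{src_site}": (tgt_site, src_site),
        }.items():
            r = knn.te_spo(
                norm[a][ep], norm[b][ep], d_x=d, d_y=d, tau=tau,
                u=u_opt[direction], k=config.k, **meta,
            )
            r.direction_or_site = direction
            r.epoch_index = ep
            records.append(r)
    return records


def _estimate_nsb(rec: Recording, d: int, tau: int, config: PipelineConfig) -> list:
    src_site, tgt_site = rec.sites
    records = []
    norm = {s: znormalize(rec.channel(s)) for s in rec.sites}
    meta = dict(condition=rec.condition, session_id=rec.session_id, epoch_index="pooled")
    for site in rec.sites:
        sym = np.stack([bayes.discretize(ep, config.n_inner_bins) for ep in norm[site]])
        wc = bayes.state_words(sym, d=1, role="present", K=config.nsb_support)
        records.append(
            knn.EstimateRecord(
                measure="H", value=bayes.nsb_entropy(wc), unit="bits",
                direction_or_site=site,
                params={"backend": "nsb", "n_bins": config.n_inner_bins}, **meta,
            )
        )
        records.append(
            knn.EstimateRecord(
                measure="AIS",
                value=bayes.ais_decomposed(
                    sym, d=d, tau=tau, K=config.nsb_support, discretized=True
                ),
                unit="bits", direction_or_site=site,
                params={"backend": "nsb", "d": d, "tau": tau}, **meta,
            )
        )
    u_mid = int(np.median(config.u_grid))
    for direction, (a, b) in {
        f"{src_site}->{tgt_site}": (src_site, tgt_site),
        f"{tgt_site}->{src_site}": (tgt_site, src_site),
    }.items():
        records.append(
            knn.EstimateRecord(
                measure="TE_SPO",
                value=bayes.te_decomposed(
                    norm[a], norm[b], d_x=d, d_y=d, tau=tau, u=u_mid,
                    n_inner_bins=config.n_inner_bins, K=config.nsb_support,
                ),
                unit="bits", direction_or_site=direction,
                params={"backend": "nsb", "d": d, "tau": tau, "u": u_mid}, **meta,
            )
        )
    return records


def _stats_stage(table: pd.DataFrame, recordings: list, config: PipelineConfig) -> dict:
    report = {}
    # surrogate test + binomial aggregation for TE on each recording
    def te_estimator(src, tgt):
        u = int(np.median(config.u_grid))
        return knn.te_spo(src, tgt, d_x=1, d_y=1, tau=1, u=u, k=config.k).value

    n_sig = 0
    per_recording = []
    for rec in recordings:
        src = znormalize(rec.channel(rec.sites[0]))[: config.surrogate_epochs]
        tgt = znormalize(rec.channel(rec.sites[1]))[: config.surrogate_epochs]
        res = stats.surrogate_test(
            src, tgt, te_estimator, n_surrogates=config.n_surrogates, seed=config.seed
        )
        sig = res.p < 0.05
        n_sig += int(sig)
        per_recording.append(
            {"session_id": rec.session_id, "observed": res.observed, "p": res.p,
             "significant": bool(sig)}
        )
    report["surrogate_te"] = {
        "per_recording": per_recording,
        "n_significant": n_sig,
        "n_recordings": len(recordings),
        "binomial_p": stats.binomial_aggregate(n_sig, len(recordings)),
        "n_surrogates": config.n_surrogates,
    }
    # pANOVA per measure on per-recording medians
    med = stats.aggregate_by_recording(table)
    report["panova"] = {}
    for measure in sorted(med["measure"].unique()):
        sub = med[med["measure"] == measure]
        try:
            res = stats.perm_anova_2way(
                sub["value"], sub["condition"], sub["direction_or_site"],
                n_perm=config.n_perm, seed=config.seed,
                factor_names=("condition", "direction_or_site"),
            )
            report["panova"][measure] = res.as_dict()
        except ParameterError as exc:
            report["panova"][measure] = {"error": str(exc)}
    # LMM comparison on per-epoch TE values
    te_tab = table[table["measure"] == "TE_SPO"]
    if te_tab["session_id"].nunique() >= 2:
        cmp_tab = stats.lmm_compare(te_tab)
        report["lmm"] = {
            "comparisons": cmp_tab.to_dict(orient="records"),
            "icc": stats.icc(te_tab),
        }
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the results bundle and writes artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    recordings = _load_inputs(config)
    qc_rows = []
    cleaned = []
    for rec in recordings:
        rec2, qcs = _qc(rec, config)
        cleaned.append(rec2)
        for q in qcs:
            qc_rows.append({"session_id": rec.session_id, **q.as_row()})
    pd.DataFrame(qc_rows).to_csv(out / "qc.tsv", sep="\t", index=False)

    if config.optimize_embedding:
        d, tau = _optimized_spec(cleaned, config)
    else:
        d, tau = config.d, config.tau

    records = []
    for rec in cleaned:
        if "knn" in config.backends:
            records.extend(_estimate_knn(rec, d, tau, config))
        if "nsb" in config.backends:
            records.extend(_estimate_nsb(rec, d, tau, config))
    table = pd.DataFrame([r.as_row() for r in records])
    table.to_csv(out / "estimates.tsv", sep="\t", index=False)

    knn_table = table[table["unit"] == "nats"] if "knn" in config.backends else table
    stats_report = _stats_stage(knn_table, cleaned, config)
    stats_report["embedding"] = {"d": d, "tau": tau}
    stats_report["seed"] = config.seed
    if "nsb" in config.backends and "knn" in config.backends:
        stats_report["backend_agreement"] = _backend_agreement(table)
    (out / "stats.json").write_text(json.dumps(stats_report, indent=1, sort_keys=True))
    return {"qc": qc_rows, "estimates": table, "stats": stats_report, "d": d, "tau": tau}


def zscore_across_conditions(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Figure-style output mode: z-score each measure across all conditions.

    Estimates of one measure are standardized jointly over every condition,
    recording and epoch so condition differences appear as z-value offsets;
    comparative statistics are unaffected by this monotone rescaling.
    """
    out = table.copy()
    for measure, idx in out.groupby("measure").groups.items():
        vals = out.loc[idx, value_col]
        sd = vals.std(ddof=0)
        out.loc[idx, value_col] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    return out


def _condition_sign(sub: pd.DataFrame) -> float:
    """Sign of the first-vs-last condition difference of mean estimates."""
    conds = sorted(sub["condition"].unique())
    lo = sub[sub["condition"] == conds[0]]["value"].mean()
    hi = sub[sub["condition"] == conds[-1]]["value"].mean()
    return float(np.sign(lo - hi))


def _backend_agreement(table: pd.DataFrame) -> dict:
    """Qualitative agreement: do both backends order the conditions alike?"""
    out = {}
    for measure in sorted(table["measure"].unique()):
        sub = table[table["measure"] == measure]
        knn_sign = _condition_sign(sub[sub["unit"] == "nats"])
        nsb_sign = _condition_sign(sub[sub["unit"] == "bits"])
        out[measure] = {
            "knn_sign": knn_sign,
            "nsb_sign": nsb_sign,
            "agree": bool(knn_sign == nsb_sign),
        }
    return out
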