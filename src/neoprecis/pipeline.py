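"""End-to-end pipeline driver and tabular interfaces.

The driver chains the synthetic world (or user tables) through triplet
curation, two-stage model training, per-mutation scoring, and patient-level
landscape computation, emitting TSV tables with a one-line ``#schema=``
header plus a JSON run manifest recording the configuration and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .immuno_model import ImmunoModelParams, TrainConfig, train_stage1, train_stage2
from .landscape import CloneCluster, LandscapeResult, TumorProfile, compute_landscape
from .mutation_metrics import MutationRecord
from .synthetic_data import (
    SyntheticConfig,
    gen_alleles_and_motifs,
    gen_cohort,
    gen_labeled_epitopes,
    gen_tcr_binding_table,
)
from .triplet_curation import make_triplets

logger = logging.getLogger(__name__)


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#schema={schema}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def mutations_to_frame(profile: TumorProfile) -> pd.DataFrame:
    rows = []
    for m in profile.mutations:
        rows.append({
            "patient_id": profile.patient_id,
            "mutation_id": m.mutation_id,
            "gene": m.gene,
            "dna_af": m.dna_af,
            "rna_af": m.rna_af,
            "tpm": m.tpm,
            "expr_quartile": m.expr_quartile,
            "phbr_i": m.phbr_i,
            "phbr_ii": m.phbr_ii,
            "robustness_i": m.robustness_i,
            "robustness_ii": m.robustness_ii,
            "agretopicity": m.agretopicity,
            "foreignness": m.foreignness,
            "np_immuno_i": m.np_immuno_i,
            "np_immuno_ii": m.np_immuno_ii,
            "np_dual": m.np_dual,
            "ccf": m.ccf,
            "cluster_id": m.cluster_id,
        })
    return pd.DataFrame(rows)


def landscape_to_frame(results: list[LandscapeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id, "tmb": r.tmb, "tnb": r.tnb, "npb": r.npb,
            "np_sum": r.np_sum, "np_ccf": r.np_ccf, "np_clone": r.np_clone,
            "csin": r.csin, "iotnl": r.iotnl,
            "s_gini": r.s_gini, "p_gini": r.p_gini,
            "pct_clonal": r.pct_clonal, "pct_binding_i": r.pct_binding_i,
            "heterogeneity_class": r.heterogeneity_class,
        }
        if r.benefit is not None:
            row.update({
                "benefit_i": r.benefit.mhc_i, "benefit_ii": r.benefit.mhc_ii,
                "benefit_dual": r.benefit.dual, "combined_score": r.benefit.combined,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def read_cluster_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> list[CloneCluster]:
    """Cluster TSV (cluster_id, prevalence[, n_mutations]); clone-inference
    output column names can be adapted via ``column_map`` (e.g.
    {"cluster_id": "cluster", "prevalence": "cellular_prevalence"})."""
    df = read_table(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return [
        CloneCluster(cluster_id=str(r.cluster_id), prevalence=float(r.prevalence))
        for r in df.itertuples(index=False)
    ]


def profiles_from_tables(
    mutation_df: pd.DataFrame,
    cluster_df: pd.DataFrame | None = None,
    hla_i: list[str] | None = None,
    hla_ii: list[str] | None = None,
) -> list[TumorProfile]:
    """Assemble per-patient profiles from a scored mutation table (and an
    optional per-patient cluster table)."""
    profiles = []
    for pid, sub in mutation_df.groupby("patient_id"):
        mutations = []
        for r in sub.to_dict("records"):
            mutations.append(MutationRecord(
                mutation_id=str(r["mutation_id"]),
                gene=str(r.get("gene", "")),
                dna_af=float(r.get("dna_af", np.nan)),
                rna_af=float(r.get("rna_af", np.nan)),
                tpm=float(r.get("tpm", np.nan)),
                expr_quartile=int(r.get("expr_quartile", 0) or 0),
                phbr_i=float(r.get("phbr_i", np.nan)),
                phbr_ii=float(r.get("phbr_ii", np.nan)),
                agretopicity=float(r.get("agretopicity", np.nan)),
                np_immuno_i=float(r.get("np_immuno_i", np.nan)),
                np_immuno_ii=float(r.get("np_immuno_ii", np.nan)),
                pmhc_ranks=json.loads(r["pmhc_ranks"]) if isinstance(r.get("pmhc_ranks"), str) else [],
                ccf=float(r.get("ccf", np.nan)),
                cluster_id=None if pd.isna(r.get("cluster_id")) else str(r["cluster_id"]),
            ))
        if cluster_df is not None:
            csub = cluster_df[cluster_df["patient_id"] == pid] if "patient_id" in cluster_df else cluster_df
            clusters = [
                CloneCluster(
                    cluster_id=str(r.cluster_id),
                    prevalence=float(r.prevalence),
                    mutation_ids={m.mutation_id for m in mutations
                                  if m.cluster_id == str(r.cluster_id)},
                )
                for r in csub.itertuples(index=False)
            ]
        else:
            # no cluster table: reconstruct clusters from the mutation
            # annotations, using the members' maximum CCF as prevalence
            clusters = []
            for cid in sorted({m.cluster_id for m in mutations if m.cluster_id}):
                members = [m for m in mutations if m.cluster_id == cid]
                ccfs = [m.ccf for m in members if not np.isnan(m.ccf)]
                clusters.append(CloneCluster(
                    cluster_id=cid,
                    prevalence=float(np.clip(max(ccfs), 0, 1)) if ccfs else 0.0,
                    mutation_ids={m.mutation_id for m in members},
                ))
        profiles.append(TumorProfile(
            patient_id=str(pid),
            hla_i=hla_i or ["HLA-A*01:01"],
            hla_ii=hla_ii or ["HLA-DRB1*01:01"],
            mutations=mutations,
            clusters=clusters,
        ))
    return profiles


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    synth: SyntheticConfig | None = None,
    train_epochs: int | None = None,
) -> dict:
    """Synthetic end-to-end run: generate a world, curate triplets and
    epitopes, train both stages, score a cohort and write the per-mutation
    and per-patient tables plus a manifest. Returns paths and summaries."""
    from .landscape import heterogeneity_class

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    synth = synth or SyntheticConfig(seed=config.seed)
    epochs = train_epochs if train_epochs is not None else config.epochs

    world = gen_alleles_and_motifs(synth)
    records, _ = gen_tcr_binding_table(synth, world)
    triplets = make_triplets(records, world.predictor, seed=synth.seed)
    params0 = ImmunoModelParams.initialize(seed=synth.seed)
    params0.margin = config.margin
    tc = TrainConfig(epochs=epochs, lr=config.lr, seed=synth.seed)
    params1, stage1_log = train_stage1(triplets, world.motifs, params0, tc,
                                       predictor=world.predictor)
    epitopes, _ = gen_labeled_epitopes(synth, world)
    from .triplet_curation import assign_splits
    labels = np.array([e.label for e in epitopes])
    splits = assign_splits(labels, (0.75, 0.10, 0.15), np.random.default_rng(synth.seed))
    epitopes = [
        type(e)(e.wt_peptide, e.mt_peptide, e.allele, e.mhc_class, e.label, s)
        for e, s in zip(epitopes, splits)
    ]
    try:
        params2, stage2_log = train_stage2(epitopes, world.motifs, world.predictor, params1, tc)
    except ValueError as exc:
        logger.warning("stage-2 training skipped: %s", exc)
        params2, stage2_log = params1, {}

    profiles, responses, _ = gen_cohort(synth, world, params=params2)
    results = [
        compute_landscape(p, integration=config.dual_integration,
                          csin_cutoffs=tuple(config.csin_cutoffs),
                          iotnl_e=config.iotnl_e)
        for p in profiles
    ]
    classes = heterogeneity_class([r.s_gini for r in results], [r.p_gini for r in results])
    for r, c in zip(results, classes):
        r.heterogeneity_class = c

    mut_df = pd.concat([mutations_to_frame(p) for p in profiles], ignore_index=True)
    land_df = landscape_to_frame(results)
    land_df["response"] = responses
    write_table(mut_df, out_dir / "mutations.tsv", "mutation_metrics.v1")
    write_table(land_df, out_dir / "landscape.tsv", "landscape.v1")
    params2.save(out_dir / "model.npz")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "synthetic_config": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in synth.__dict__.items()},
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_triplets": len(triplets),
        "n_epitopes": len(epitopes),
        "n_patients": len(profiles),
        "stage1_final_loss": stage1_log[-1] if stage1_log else None,
        "stage2_best_val_loss": (min(stage2_log["val_loss"]) if stage2_log else None),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "mutations": out_dir / "mutations.tsv",
        "landscape": out_dir / "landscape.tsv",
        "manifest": manifest,
        "results": results,
    }
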