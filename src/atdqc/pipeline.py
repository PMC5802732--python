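"""Pipeline orchestration: validated config in, files + combined report out.

Stages exchange files rather than in-memory objects so each can be rerun
independently; the machine-readable JSON report is the contract, logs are
not. Two runs with the same config and inputs produce byte-identical
per-stage TSV/JSON outputs (wall-clock timestamps are confined to the
report's provenance block).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from . import io as aio
from . import family as fam
from . import kinetics as kin
from . import structure as struct
from . import synthetic as synth
from . import wobble as wob

logger = logging.getLogger("atdqc")

__all__ = ["ConfigError", "RunConfig", "validate_config", "run_all"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


_STAGE_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {"enabled": False},
    "structure": {
        "enabled": False,
        "files": [],
        "reference": None,
        "prune_cutoff": 3.5,
        "contact_cutoff": 3.5,
        "format": "auto",
    },
    "classify": {"enabled": False, "fasta": None, "max_mismatch": 1},
    "wobble": {
        "enabled": False,
        "genes": None,
        "presence": None,
        "enrichment_table": None,
        "isotype": "Thr",
        "score_min": 50.0,
        "enrich_threshold": 10.0,
    },
    "kinetics": {
        "enabled": False,
        "data": None,
        "depletion_threshold": 0.5,
        "noncognate_substrate": "L-Ala-tRNA-Thr-G4U69",
        "cognate_substrate": "L-Thr-tRNA-Thr-G4U69",
    },
}

_TOP_KEYS = {"seed", "outdir", "stages"}


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: dict[str, dict[str, Any]]
    source_hash: str = ""

    def enabled(self, stage: str) -> bool:
        return bool(self.stages[stage]["enabled"])


def _range_problems(stages: dict[str, dict[str, Any]]) -> list[str]:
    problems = []
    s = stages["structure"]
    if s["prune_cutoff"] is not None and not s["prune_cutoff"] > 0:
        problems.append("structure.prune_cutoff must be > 0")
    if not s["contact_cutoff"] > 0:
        problems.append("structure.contact_cutoff must be > 0")
    if s["format"] not in ("pdb", "mmcif", "auto"):
        problems.append("structure.format must be pdb|mmcif|auto")
    if stages["classify"]["max_mismatch"] < 0:
        problems.append("classify.max_mismatch must be >= 0")
    w = stages["wobble"]
    if not 0.0 <= w["enrich_threshold"] <= 100.0:
        problems.append("wobble.enrich_threshold must be in [0, 100]")
    k = stages["kinetics"]
    if not 0.0 < k["depletion_threshold"] <= 1.0:
        problems.append("kinetics.depletion_threshold must be in (0, 1]")
    return problems


def validate_config(path) -> RunConfig:
    """Parse + normalize a YAML run config; fail hard on unknown keys,
    out-of-range thresholds, and missing input paths, reporting all
    problems at once."""
    raw_text = Path(path).read_text()
    raw = yaml.safe_load(raw_text) or {}
    problems: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level key(s): {sorted(unknown)}")
    stages_in = raw.get("stages") or {}
    if set(stages_in) - set(_STAGE_DEFAULTS):
        problems.append(
            f"unknown stage(s): {sorted(set(stages_in) - set(_STAGE_DEFAULTS))}"
        )
    stages: dict[str, dict[str, Any]] = {}
    for name, defaults in _STAGE_DEFAULTS.items():
        given = stages_in.get(name) or {}
        if not isinstance(given, dict):
            problems.append(f"stage {name!r} must be a mapping")
            given = {}
        extra = set(given) - set(defaults)
        if extra:
            problems.append(f"stage {name!r}: unknown key(s) {sorted(extra)}")
        merged = {**defaults, **{k: v for k, v in given.items() if k in defaults}}
        stages[name] = merged
    if problems:
        raise ConfigError("; ".join(problems))
    problems.extend(_range_problems(stages))
    # referenced input paths must exist unless the simulate stage will
    # produce them into the output directory
    simulate_on = stages["simulate"]["enabled"]
    path_keys = {
        "structure": ["reference"],
        "classify": ["fasta"],
        "wobble": ["genes", "presence", "enrichment_table"],
        "kinetics": ["data"],
    }
    for stage, keys in path_keys.items():
        if not stages[stage]["enabled"]:
            continue
        for key in keys + (["files"] if stage == "structure" else []):
            val = stages[stage][key]
            paths = val if isinstance(val, list) else ([val] if val else [])
            for p in paths:
                if not Path(p).exists():
                    problems.append(f"{stage}.{key}: path does not exist: {p}")
        needs_input = any(stages[stage][k] for k in keys) or (
            stage == "structure" and stages[stage]["files"]
        )
        if not needs_input and not simulate_on:
            problems.append(
                f"stage {stage!r} enabled without inputs and without the simulate stage"
            )
    if problems:
        raise ConfigError("; ".join(problems))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        outdir=Path(raw.get("outdir", "atdqc_out")),
        stages=stages,
        source_hash=hashlib.sha256(raw_text.encode()).hexdigest(),
    )


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    sd = outdir / "synthetic"
    sd.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    atd = synth.build_deacylase_dimer("ATD", seed=seed)
    dtd = synth.build_deacylase_dimer("DTD", seed=seed)
    (sd / "atd_dimer.pdb").write_text(struct.write_pdb(atd))
    (sd / "dtd_dimer.pdb").write_text(struct.write_pdb(dtd))
    records = synth.gen_family_sequences(5, "ATD", 0.05, seed=seed) + synth.gen_family_sequences(
        5, "DTD", 0.05, seed=seed + 1
    )
    aio.write_fasta(records, sd / "family.fasta")
    genes = synth.gen_trna_set(
        {"Thr": 40, "Cys": 40, "Ala": 40},
        {"Thr": 0.30, "Cys": 0.05, "Ala": 0.0},
        seed=seed,
    )
    aio.genes_to_tsv(genes, sd / "genes.tsv")
    rows, presence = synth.gen_presence_table(24, concordance=1.0, seed=seed)
    aio.enrichment_to_tsv(rows, sd / "enrichment_multi.tsv")
    aio.presence_to_tsv(presence, sd / "presence.tsv")
    # paper-condition dose ladders: non-cognate effective at 1 nM, cognate
    # at 50 nM; activated EF-Tu shifts them to 50 nM and 5000 nM
    ladder = (0.2, 1.0, 5.0, 50.0, 200.0, 500.0, 5000.0)
    series = (
        synth.gen_dose_ladder(0.02, ladder, noise_sd=0.02, seed=seed, substrate="L-Ala-tRNA-Thr-G4U69")
        + synth.gen_dose_ladder(0.02 / 50.0, ladder, noise_sd=0.02, seed=seed + 2, substrate="L-Thr-tRNA-Thr-G4U69")
        + synth.gen_dose_ladder(0.02, ladder, noise_sd=0.02, seed=seed + 3, substrate="L-Ala-tRNA-Thr-G4U69", eftu="activated", protection=50.0)
        + synth.gen_dose_ladder(0.02 / 50.0, ladder, noise_sd=0.02, seed=seed + 4, substrate="L-Thr-tRNA-Thr-G4U69", eftu="activated", protection=100.0)
    )
    aio.timecourses_to_tsv(series, sd / "kinetics.tsv")
    return {
        "outputs": sorted(p.name for p in sd.iterdir()),
        "n_sequences": len(records),
        "n_trna_genes": len(genes),
        "n_timecourses": len(series),
    }


def _structure_summary(st, prune_cutoff, contact_cutoff, reference):
    sites = struct.find_glypro_motifs(st)
    site_info = []
    for s in sites:
        entry = {
            "donor_chain": s.donor_chain,
            "acceptor_chain": s.acceptor_chain,
            "gly": [s.gly_ref.seq_id, s.gly_ref.icode],
            "pro": [s.pro_ref.seq_id, s.pro_ref.icode],
            "cross_subunit": s.cross_subunit,
            "omega": None if s.bond_call is None else round(s.bond_call.omega, 3),
            "conformation": None if s.bond_call is None else s.bond_call.conformation,
        }
        try:
            ori = struct.carbonyl_orientation(s, st)
            entry["orientation"] = {
                "parallelism_angle": round(ori.parallelism_angle, 3),
                "mean_projection": round(ori.mean_projection, 4),
                "label": ori.label,
            }
        except ValueError:
            entry["orientation"] = None
        try:
            rig = struct.motif_rigidity(st, s)
            entry["rigidity_z"] = round(rig.motif_z, 4)
        except ValueError:
            entry["rigidity_z"] = None
        site_info.append(entry)
    out = {
        "id": st.id,
        "n_polymer_chains": len(st.polymer_chains),
        "n_polymer_residues": st.n_polymer_residues,
        "glypro_sites": site_info,
    }
    if reference is not None:
        rep = struct.align_and_superpose(reference, st, prune_cutoff=prune_cutoff)
        out["superposition_vs_reference"] = {
            "rmsd": round(rep.rmsd, 4),
            "n_pairs": rep.n_pairs,
            "n_iterations": rep.n_iterations,
        }
    return out


def _stage_structure(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.stages["structure"]
    files = [Path(f) for f in p["files"]] or [outdir / "synthetic" / "atd_dimer.pdb"]
    ref_path = p["reference"]
    if ref_path is None and cfg.enabled("simulate"):
        ref_path = outdir / "synthetic" / "dtd_dimer.pdb"
    reference = (
        struct.read_structure(ref_path, p["format"]) if ref_path else None
    )
    summaries = []
    for f in files:
        st = struct.read_structure(f, p["format"])
        struct.torsion_table(st).to_csv(
            outdir / f"{Path(f).stem}_torsions.tsv", sep="\t", index=False
        )
        summaries.append(
            _structure_summary(st, p["prune_cutoff"], p["contact_cutoff"], reference)
        )
    (outdir / "structure_summary.json").write_text(
        json.dumps({"structures": summaries}, indent=2) + "\n"
    )
    return {"n_structures": len(summaries), "structures": summaries}


def _stage_classify(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.stages["classify"]
    fasta = Path(p["fasta"]) if p["fasta"] else outdir / "synthetic" / "family.fasta"
    records = aio.read_fasta(fasta)
    patterns = [
        dataclasses.replace(pat, max_mismatch=int(p["max_mismatch"]))
        for pat in fam.DEFAULT_PATTERNS
    ]
    rows = []
    for rec in records:
        try:
            call = fam.classify_family(rec, patterns)
        except ValueError as exc:
            rows.append({"id": rec.id, "family": "error", "score": "", "motifs": str(exc), "anchors": ""})
            continue
        anchors = ""
        if call.family in ("DTD", "ATD"):
            located = fam.anchor_residue(rec, call)
            anchors = ";".join(
                f"{a.label}={a.residue}@{a.position}" if a.resolved else f"{a.label}=unresolved"
                for a in located
            )
        motifs = ";".join(
            f"{h.pattern.family}{h.pattern.motif_index}@{h.start}mm{h.mismatches}"
            for h in call.hits
            if h.is_best
        )
        rows.append(
            {"id": rec.id, "family": call.family, "score": call.score, "motifs": motifs, "anchors": anchors}
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "family_calls.tsv", sep="\t", index=False)
    counts: dict[str, int] = {}
    for r in rows:
        counts[r["family"]] = counts.get(r["family"], 0) + 1
    return {"n_records": len(rows), "family_counts": counts}


def _stage_wobble(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.stages["wobble"]
    genes_path = Path(p["genes"]) if p["genes"] else outdir / "synthetic" / "genes.tsv"
    presence_path = (
        Path(p["presence"]) if p["presence"] else outdir / "synthetic" / "presence.tsv"
    )
    genes = wob.filter_by_score(
        wob.read_trna_table(genes_path), float(p["score_min"])
    )
    rows = wob.enrichment(genes)
    aio.enrichment_to_tsv(rows, outdir / "enrichment.tsv")
    co_rows = rows
    et = p["enrichment_table"]
    if et is None and cfg.enabled("simulate"):
        et = outdir / "synthetic" / "enrichment_multi.tsv"
    if et is not None and Path(et).exists():
        import pandas as pd

        df = pd.read_csv(et, sep="\t")
        co_rows = [
            wob.EnrichmentRow(r.organism, r.isotype, int(r.n_total), int(r.n_wobble))
            for r in df.itertuples(index=False)
        ]
    presence = aio.read_presence(presence_path)
    report = wob.cooccurrence(
        co_rows, presence, float(p["enrich_threshold"]), p["isotype"]
    )
    consensus = wob.acceptor_consensus(
        [g for g in genes if g.isotype == p["isotype"]]
    ) if any(g.isotype == p["isotype"] for g in genes) else None
    summary = {
        "n_genes_after_filter": len(genes),
        "enrichment": [
            {"organism": r.organism, "isotype": r.isotype, "n_total": r.n_total,
             "n_wobble": r.n_wobble, "fraction": round(r.fraction, 3)}
            for r in rows
        ],
        "cooccurrence": {
            "table": report.table,
            "concordance": report.concordance,
            "fisher_p": report.fisher_p,
        },
        "acceptor_consensus": None
        if consensus is None
        else [
            {"pair": i + 1, "modal": list(pair), "frequency": round(freq, 4)}
            for i, (pair, freq) in enumerate(consensus.conservation)
        ],
    }
    (outdir / "wobble_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _stage_kinetics(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.stages["kinetics"]
    data = Path(p["data"]) if p["data"] else outdir / "synthetic" / "kinetics.tsv"
    series = aio.read_timecourses(data)
    thr = float(p["depletion_threshold"])
    import pandas as pd

    fits = []
    for tc in series:
        f = kin.fit_decay(tc)
        fits.append(
            {
                "substrate": tc.substrate,
                "enzyme_conc_nM": tc.enzyme_conc,
                "eftu": tc.eftu,
                "k_obs": f.k_obs,
                "s0": f.s0,
                "rmse": f.rmse,
                "converged": f.converged,
            }
        )
    pd.DataFrame(fits).to_csv(outdir / "decay_fits.tsv", sep="\t", index=False)

    def pick(substrate, eftu):
        return [tc for tc in series if tc.substrate == substrate and tc.eftu == eftu]

    non, cog = p["noncognate_substrate"], p["cognate_substrate"]
    summary: dict[str, Any] = {"n_timecourses": len(series)}
    for eftu in ("none", "activated", "unactivated"):
        ns, cs = pick(non, eftu), pick(cog, eftu)
        if ns and cs:
            d = kin.discrimination_factor(ns, cs, thr)
            summary[f"discrimination_{eftu}"] = {
                "conc_noncognate_nM": d.conc_noncognate,
                "conc_cognate_nM": d.conc_cognate,
                "factor": d.factor,
                "message": d.message,
            }
    free, shielded = pick(cog, "none"), pick(cog, "activated")
    if free and shielded:
        summary["protection_factor_cognate"] = kin.protection_factor(free, shielded, thr)
    (outdir / "kinetics_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "structure": _stage_structure,
    "classify": _stage_classify,
    "wobble": _stage_wobble,
    "kinetics": _stage_kinetics,
}

_STAGE_ORDER = ("simulate", "structure", "classify", "wobble", "kinetics")


def run_all(cfg: RunConfig) -> dict:
    """Run every enabled stage in dependency order and write the report.

    A stage failure is recorded in the report and independent stages still
    run; the returned report carries ``n_failures`` so callers can set a
    non-zero exit code on hard errors.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "stages": {},
        "warnings": [],
        "provenance": {
            "tool": "atdqc",
            "version": __version__,
            "seed": cfg.seed,
            "config_sha256": cfg.source_hash,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    }
    enabled = [s for s in _STAGE_ORDER if cfg.enabled(s)]
    if not enabled:
        report["warnings"].append("no stages enabled: empty report")
    failures = 0
    for stage in enabled:
        logger.info("running stage %s", stage)
        try:
            report["stages"][stage] = {"status": "ok", "summary": _STAGE_FUNCS[stage](cfg, outdir)}
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            failures += 1
    report["n_failures"] = failures
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
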