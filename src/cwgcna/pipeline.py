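"""End-to-end orchestration: modules -> differential -> mediation -> annotation.

One call runs the full causal co-expression workflow on a matrix plus
phenotype table and writes every result table (TSV with version/seed header)
under an output directory, together with ``manifest.json`` listing each
artifact with its SHA-256 checksum, the configuration and the seed. Stage
order is fixed; disabling mediation or annotation never changes upstream
outputs; re-running with the same inputs and seed reproduces every table
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .annotate import (
    build_edge_term_map,
    combine_edge_term_maps,
    edge_hypergeom_test,
    edge_shuffle_test,
)
from .datamodel import GeneSetCollection, OmicsMatrix, PhenotypeTable
from .diffstats import diff_features_within_module, diff_modules
from .io import write_table
from .mediation import causal_screen
from .network import build_modules

__all__ = ["RunConfig", "run_causal_wgcna"]

log = logging.getLogger("cwgcna")


@dataclass
class RunConfig:
    """Parameters of one causal co-expression run."""

    out_dir: str
    seed: int = 0
    # network
    soft_power: int | None = None
    signed: bool = False
    min_module_size: int = 30
    cut_height: float = 0.9
    r2_cut: float = 0.8
    # differential
    alpha: float = 0.05
    # mediation
    mediation: bool = True
    n_boot: int = 1000
    doubly_robust: bool = False
    # annotation
    annotation_method: str = "shuffle"  # or "hypergeom"
    n_shuffle: int = 1000
    min_edge_weight: float = 0.0
    extra: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_causal_wgcna(
    cfg: RunConfig,
    m: OmicsMatrix,
    ph: PhenotypeTable,
    gene_sets: GeneSetCollection | None = None,
) -> dict:
    """Execute the pipeline and return the manifest (also written to disk).

    Stages: module detection; eigengene differential testing; within-module
    feature differential testing for each significant module; two-direction
    mediation per significant module (when ``cfg.mediation``); edge-based
    gene-set annotation per significant module (when gene sets are given).
    A stage failure aborts with the stage name; partial outputs are kept.
    """
    out = Path(cfg.out_dir)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        out.mkdir(parents=True, exist_ok=True)
        ph = ph.align_to(m)

        stage = "modules"
        (out / "modules").mkdir(exist_ok=True)
        ms = build_modules(
            m, beta=cfg.soft_power, signed=cfg.signed,
            min_size=cfg.min_module_size, cut_height=cfg.cut_height, r2_cut=cfg.r2_cut,
        )
        log.info("stage modules: %d module(s) detected", len(ms.module_labels))
        p = out / "modules" / "assignment.tsv"
        write_table(ms.assignment_frame(), p, seed=cfg.seed, index=False)
        artifacts.append(p)
        p = out / "modules" / "eigengenes.tsv"
        write_table(ms.eigengenes.rename_axis("module"), p, seed=cfg.seed)
        artifacts.append(p)

        stage = "diff"
        (out / "diff").mkdir(exist_ok=True)
        dmod = diff_modules(ms, ph, alpha=cfg.alpha)
        p = out / "diff" / "modules.tsv"
        write_table(dmod, p, seed=cfg.seed, index=False)
        artifacts.append(p)
        sig_modules = dmod.loc[dmod["significant"], "unit"].tolist()
        log.info("stage diff: %d differential module(s): %s", len(sig_modules), sig_modules)
        feature_tables = {}
        for mod in sig_modules:
            dfeat = diff_features_within_module(m, ms, mod, ph, alpha=cfg.alpha)
            feature_tables[mod] = dfeat
            p = out / "diff" / f"features_{mod}.tsv"
            write_table(dfeat, p, seed=cfg.seed, index=False)
            artifacts.append(p)

        if cfg.mediation:
            stage = "mediation"
            (out / "mediation").mkdir(exist_ok=True)
            for i, mod in enumerate(sig_modules):
                med = causal_screen(
                    m, ms, mod, feature_tables[mod], ph,
                    n_boot=cfg.n_boot, seed=cfg.seed + i, alpha=cfg.alpha,
                    doubly_robust=cfg.doubly_robust,
                )
                p = out / "mediation" / f"{mod}.tsv"
                write_table(med, p, seed=cfg.seed, index=False)
                artifacts.append(p)
                n_drv = med.loc[med["direction"] == "forward", "label"].eq("driver").sum()
                log.info("stage mediation: module %s, %d driver call(s)", mod, n_drv)

        if gene_sets is not None:
            stage = "annotation"
            (out / "annotation").mkdir(exist_ok=True)
            etms = {
                mod: build_edge_term_map(ms, mod, gene_sets, min_weight=cfg.min_edge_weight)
                for mod in ms.module_labels
            }
            for mod in sig_modules:
                etm = etms[mod]
                if cfg.annotation_method == "shuffle":
                    res = edge_shuffle_test(etm, n_shuffle=cfg.n_shuffle, seed=cfg.seed)
                else:
                    background = combine_edge_term_maps(list(etms.values()))
                    res = edge_hypergeom_test(etm, background)
                p = out / "annotation" / f"{mod}.tsv"
                write_table(res, p, seed=cfg.seed, index=False)
                artifacts.append(p)

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "config": {k: v for k, v in asdict(cfg).items() if k != "extra"},
            "modules": ms.module_labels,
            "differential_modules": sig_modules,
            "artifacts": [
                {"path": str(a.relative_to(out)), "sha256": _sha256(a)} for a in artifacts
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
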