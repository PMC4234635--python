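"""End-to-end orchestration: simulate (or load) -> exact test -> enrichment.

One plain-text ``key = value`` config drives a full run; every threshold
and set size used is echoed into a JSON manifest next to the output
tables, so each reported number is recomputable from the referenced
inputs.  Runs are deterministic: the same config produces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .diffexpr import DegThresholds, call_degs
from .enrichment import enrich_terms
from .io import (
    TermAssignment,
    LibraryPair,
    read_count_table,
    read_term_table,
    write_count_table,
    write_results,
)
from .synthetic import SimulationConfig, SyntheticTruth, simulate_pair, simulate_terms

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "read_config", "run_all"]

_SIM_FIELDS = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to audit one pipeline run."""

    version: str
    inputs: dict
    thresholds: dict
    n_genes: int
    n_tested: int
    n_up: int
    n_down: int
    n_ns: int
    namespaces: dict  # per namespace: {"N": universe size, "n": DEGs in universe}
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a ``key = value`` config file; '#' starts a comment."""
    config: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in config:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        config[key] = value
    return config


def _coerce_sim_config(config: dict[str, str]) -> SimulationConfig:
    kwargs: dict = {}
    for name in _SIM_FIELDS:
        if name not in config:
            continue
        raw = config[name]
        if name in ("length_range_bp", "term_size_range"):
            lo, hi = (int(v) for v in raw.split(","))
            kwargs[name] = (lo, hi)
        elif name == "expression_shape":
            kwargs[name] = None if raw.lower() in ("none", "flat") else float(raw)
        elif name == "length_weighted":
            kwargs[name] = raw.lower() in ("1", "true", "yes")
        elif name in ("de_fraction", "log2_fc_magnitude", "planted_odds", "overdispersion"):
            kwargs[name] = float(raw)
        else:
            kwargs[name] = int(raw)
    return SimulationConfig(**kwargs)


def _attach_planted(
    truth: list[SyntheticTruth], assignments: list[TermAssignment], planted: list[str]
) -> list[SyntheticTruth]:
    planted_set = set(planted)
    by_gene: dict[str, list[str]] = {}
    for a in assignments:
        if a.term_id in planted_set:
            by_gene.setdefault(a.gene_id, []).append(a.term_id)
    return [
        dataclasses.replace(t, planted_term_ids=tuple(sorted(by_gene.get(t.gene_id, ()))))
        for t in truth
    ]


def run_all(config_path: str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute simulate/load -> DEG test -> per-namespace enrichment.

    Writes ``deg.tsv``, ``enrichment.tsv`` and ``manifest.json`` (plus
    ``sim.counts.tsv`` / ``sim.terms.tsv`` / ``sim.truth.tsv`` for
    synthetic runs) into ``out_dir`` (default: the config's directory).
    """
    config_path = Path(config_path)
    config = read_config(config_path)
    out = Path(out_dir) if out_dir is not None else config_path.parent
    out.mkdir(parents=True, exist_ok=True)

    thresholds = DegThresholds(
        fdr_max=float(config.get("fdr_max", 1e-3)),
        min_abs_log2=float(config.get("min_abs_log2", 1.0)),
    )
    pseudo = float(config.get("pseudo", 0.0))
    p_max = float(config.get("p_max", 0.05))
    q_max = float(config.get("q_max", 0.05))

    inputs: dict = {}
    seed: int | None = None
    if "counts" in config:
        log.info("stage load: reading %s", config["counts"])
        counts_path = (config_path.parent / config["counts"]).resolve()
        pair = read_count_table(counts_path)
        inputs["counts"] = str(counts_path)
        assignments: list[TermAssignment] = []
        if "terms" in config:
            terms_path = (config_path.parent / config["terms"]).resolve()
            assignments = read_term_table(terms_path)
            inputs["terms"] = str(terms_path)
    else:
        sim = _coerce_sim_config(config)
        seed = sim.seed
        log.info("stage simulate: %d genes, seed %d", sim.n_genes, sim.seed)
        pair, truth = simulate_pair(sim)
        assignments, planted = simulate_terms(truth, sim)
        truth = _attach_planted(truth, assignments, planted)
        write_count_table(pair, out / "sim.counts.tsv")
        write_results(assignments, out / "sim.terms.tsv")
        write_results(truth, out / "sim.truth.tsv")
        inputs["simulation"] = dataclasses.asdict(sim)
        inputs["planted_term_ids"] = planted

    log.info("stage detest: %d genes", len(pair))
    degs = call_degs(pair, thresholds, pseudo)
    write_results(degs, out / "deg.tsv")
    deg_ids = {d.gene_id for d in degs if d.status != "ns"}

    namespaces: dict[str, dict[str, int]] = {}
    enrichment_records = []
    for namespace in sorted({a.namespace for a in assignments}):
        log.info("stage enrich: namespace %s", namespace)
        records = enrich_terms(deg_ids, assignments, namespace, p_max, q_max)
        enrichment_records.extend(records)
        if records:
            namespaces[namespace] = {"N": records[0].N, "n": records[0].n}
    if assignments:
        write_results(enrichment_records, out / "enrichment.tsv")

    n_tested = sum(1 for d, g in zip(degs, pair.genes) if g.count_a + g.count_b > 0)
    manifest = RunManifest(
        version=__version__,
        inputs=inputs,
        thresholds={
            "fdr_max": thresholds.fdr_max,
            "min_abs_log2": thresholds.min_abs_log2,
            "pseudo": pseudo,
            "p_max": p_max,
            "q_max": q_max,
        },
        n_genes=len(pair),
        n_tested=n_tested,
        n_up=sum(d.status == "up" for d in degs),
        n_down=sum(d.status == "down" for d in degs),
        n_ns=sum(d.status == "ns" for d in degs),
        namespaces=namespaces,
        seed=seed,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest
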