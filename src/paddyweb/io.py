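"""File I/O for the pipeline's table, network and report formats.

Conventions: TSV for taxon tables (taxa as rows, samples as columns),
CSV for chemistry and qPCR series, GraphML (primary) and GEXF
(secondary, Gephi-compatible) for networks, YAML for scenarios, JSON
for the run report.  UTF-8 throughout, "." decimal separator, missing
values as empty fields.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import pandas as pd
import yaml

import paddyweb
from paddyweb.conet import AbundanceTable, CoNetwork
from paddyweb.errors import ValidationError

logger = logging.getLogger(__name__)

CHEMISTRY_COLUMNS = [
    "day", "replicate", "temperature_C", "pH",
    "acetate_mM", "propionate_mM", "pH2_kPa", "pCO2_kPa", "pCH4_kPa",
]


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


def read_counts_table(
    counts_path: str | Path, taxonomy_path: str | Path, metadata_path: str | Path
) -> AbundanceTable:
    """Assemble an AbundanceTable from its three TSV files.

    ``counts``: first column taxon id, remaining columns one per sample.
    ``taxonomy``: columns (taxon, lineage).  ``metadata``: columns
    (sample, day, temperature_C, replicate).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxon ids in counts table: {dups}")
    bad = counts.columns[(counts < 0).any(axis=0)].tolist()
    if bad:
        raise ValidationError(f"negative counts in samples: {bad}")
    tax = pd.read_csv(taxonomy_path, sep="\t")
    for col in ("taxon", "lineage"):
        if col not in tax.columns:
            raise ValidationError(f"taxonomy table lacks column {col!r}")
    lineage = dict(zip(tax["taxon"].astype(str), tax["lineage"].astype(str)))
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample" not in meta.columns:
        raise ValidationError("metadata table lacks column 'sample'")
    if meta["sample"].duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    meta = meta.set_index("sample")
    counts.index = counts.index.astype(str)
    return AbundanceTable(counts, lineage, meta)


def write_counts_table(
    table: AbundanceTable,
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write the three TSVs consumed by :func:`read_counts_table`."""
    out = table.counts.copy()
    out.index.name = "taxon"
    out.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"taxon": list(table.lineage), "lineage": [table.lineage[t] for t in table.lineage]}
    ).to_csv(taxonomy_path, sep="\t", index=False)
    meta = table.metadata.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# Chemistry
# ---------------------------------------------------------------------------


def read_chemistry(path: str | Path) -> pd.DataFrame:
    """Read a chemistry CSV and validate its schema."""
    chem = pd.read_csv(path)
    missing = set(CHEMISTRY_COLUMNS) - {"pH"} - set(chem.columns)
    if missing:
        raise ValidationError(f"chemistry table lacks columns: {sorted(missing)}")
    for col in ("acetate_mM", "propionate_mM", "pH2_kPa", "pCO2_kPa", "pCH4_kPa"):
        bad = chem.index[chem[col] < 0].tolist()
        if bad:
            raise ValidationError(f"negative {col} in rows {bad}")
    if chem.duplicated(subset=["day", "replicate", "temperature_C"]).any():
        raise ValidationError("duplicate (day, replicate, temperature) rows in chemistry table")
    return chem


def write_chemistry(chem: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CHEMISTRY_COLUMNS if c in chem.columns]
    chem[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def _export_graph(net: CoNetwork) -> nx.Graph:
    # copy with nodes/edges in sorted order so serialisation is
    # byte-stable across runs
    g = nx.Graph()
    for n in sorted(net.graph.nodes):
        g.add_node(n, **net.graph.nodes[n])
    for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
        g.add_edge(u, v, **net.graph.edges[u, v])
    g.graph["rho_min"] = net.rho_min
    g.graph["rho_max"] = net.rho_max
    g.graph["alpha"] = net.alpha
    if net.modularity_score is not None:
        g.graph["modularity"] = net.modularity_score
    return g


def write_graphml(net: CoNetwork, path: str | Path) -> None:
    """GraphML export (node attrs: degree, module, mean_abundance;
    edge attrs: rho, q)."""
    nx.write_graphml(_export_graph(net), path, infer_numeric_types=True)


def write_gexf(net: CoNetwork, path: str | Path) -> None:
    """GEXF export for Gephi."""
    g = _export_graph(net)
    # GEXF cannot serialise NaN attribute values
    for n, d in g.nodes(data=True):
        if "mean_abundance" in d and pd.isna(d["mean_abundance"]):
            del d["mean_abundance"]
    nx.write_gexf(g, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# Scenario YAML and run report
# ---------------------------------------------------------------------------


def write_report(results: Mapping[str, Any], path: str | Path) -> None:
    """Single-JSON run report: package version, config echo, per-stage
    summaries.  Keys are sorted so a fully seeded run is byte-stable."""
    payload = {"package": "paddyweb", "version": paddyweb.__version__, **results}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)!r}")


def scenario_to_yaml(scenario: "synth.Scenario", path: str | Path) -> None:
    """Serialise a full Scenario (kinetics, community plan, seeds)."""
    import dataclasses

    payload = dataclasses.asdict(scenario)
    for mod in payload["community"]:
        mod["lineages"] = dict(mod["lineages"])
        mod["base_abundance"] = {k: float(v) for k, v in mod["base_abundance"].items()}
    payload["pool_profiles"] = {
        pool: {float(d): float(f) for d, f in prof.items()}
        for pool, prof in payload["pool_profiles"].items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def scenario_from_yaml(path: str | Path) -> "synth.Scenario":
    """Load a Scenario written by :func:`scenario_to_yaml`."""
    from paddyweb import synth

    raw = yaml.safe_load(Path(path).read_text())
    community = tuple(
        synth.ModulePlan(
            name=m["name"],
            peak_day=float(m["peak_day"]),
            width_days=float(m["width_days"]),
            families=tuple(m["families"]),
            lineages=dict(m["lineages"]),
            base_abundance=dict(m["base_abundance"]),
            noise_sd=float(m.get("noise_sd", 0.2)),
        )
        for m in raw.get("community", [])
    )
    kinetics = synth.ChemKineticParams(**raw["kinetics"])
    return synth.Scenario(
        temperature_C=float(raw["temperature_C"]),
        kinetics=kinetics,
        days=tuple(raw.get("days", synth.STUDY_DAYS)),
        replicates=int(raw.get("replicates", 3)),
        community=community,
        library_size=int(raw.get("library_size", 50_000)),
        total_rna_reads=int(raw.get("total_rna_reads", 200_000)),
        pool_profiles=raw.get("pool_profiles", {}),
        pool_noise_sd=float(raw.get("pool_noise_sd", 0.1)),
        chem_noise_sd=float(raw.get("chem_noise_sd", 0.0)),
        seed=int(raw.get("seed", 0)),
    )


def read_run_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration with threshold validation."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    checks = {
        "rho_min": (0.0, 1.0), "rho_max": (0.0, 1.0), "alpha": (0.0, 1.0),
        "prevalence": (0.0, 1.0), "ph": (0.0, 14.0),
    }
    for key, (lo, hi) in checks.items():
        if key in cfg and not (lo <= float(cfg[key]) <= hi):
            raise ValidationError(f"config {key}={cfg[key]} outside [{lo}, {hi}]")
    if "seed" in cfg and int(cfg["seed"]) < 0:
        raise ValidationError("seed must be a non-negative integer")
    return cfg
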