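"""End-to-end analysis driver and structured outputs.

:func:`run` chains parse → recode → network → metrics → permutation nulls →
tree comparison → regionalization, writing a bundle of TSV/JSON/GraphML
files.  :func:`fisher_regionalization` tests whether unstable traits (type
II in-degree zero) concentrate in one body-region group (e.g. cranio-dental
vs. postcranial) with a two-sided Fisher exact test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import fisher_exact

from .matrix import (
    CharacterMatrix,
    default_absence_matcher,
    parse_nexus,
    parse_table,
    recode,
    write_trait_matrix,
)
from .metrics import DegreeRecord, summarize
from .network import build_network, edge_table
from .nulls import (
    NODE_STATISTICS,
    STANDARD_STATISTICS,
    bonferroni,
    check_permutation_count,
    null_distribution,
    patristic_weights,
    significant_pivotal_traits,
    significant_stable_traits,
)
from .phylo import classify_nested_pairs, parse_newick

__all__ = ["RunConfig", "run", "fisher_regionalization", "load_region_map"]

logger = logging.getLogger("traitgraph")


@dataclass
class RunConfig:
    matrix_path: Path
    out_dir: Path
    tree_path: Path | None = None
    regions_path: Path | None = None
    region_split: tuple[tuple[str, ...], tuple[str, ...]] = (
        ("S", "T", "J"),  # cranio-dental
        ("BP", "FL", "HL"),  # postcranial
    )
    absence_tokens: tuple[str, ...] = ()
    use_default_absence_matcher: bool = True
    min_taxa: int = 1
    M: int = 5000
    k: float = 1.01
    alpha: float = 0.05
    seed: int = 0
    delimiter: str | None = None  # None → NEXUS input

    def absence_matcher(self):
        tokens = {t.lower() for t in self.absence_tokens}

        def matcher(symbol: str, label: str) -> bool:
            if symbol.lower() in tokens or label.lower() in tokens:
                return True
            if self.use_default_absence_matcher:
                return default_absence_matcher(symbol, label)
            return False

        return matcher


def load_region_map(text: str) -> dict[int, str]:
    """Two-column TSV ``node_id<TAB>region`` → mapping."""
    out: dict[int, str] = {}
    for line in text.strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        if a == "node_id":
            continue
        out[int(a)] = b.strip()
    return out


def fisher_regionalization(
    region_map: dict[int, str],
    degrees: list[DegreeRecord],
    region_split: tuple[tuple[str, ...], tuple[str, ...]],
) -> tuple[float, np.ndarray]:
    """Two-sided Fisher exact test of unstable-trait regionalization.

    Builds the 2×2 table [unstable, not-unstable] × [group-1 regions,
    group-2 regions], where "unstable" means type II in-degree 0 (with
    positive out-degree or not — in-degree alone decides, matching the
    red/blue split of the body-plan mapping).  Returns (p, table).  An empty
    margin yields p = 1 with a warning.
    """
    unmapped = [r.node_id for r in degrees if r.node_id not in region_map]
    if unmapped:
        raise ValueError(f"nodes without region annotation: {unmapped[:10]}")
    g1, g2 = (set(g) for g in region_split)
    table = np.zeros((2, 2), dtype=np.int64)
    for r in degrees:
        region = region_map[r.node_id]
        if region in g1:
            col = 0
        elif region in g2:
            col = 1
        else:
            raise ValueError(f"region {region!r} not in either split group")
        row = 0 if r.in_degree == 0 else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty margin in regionalization table; p = 1")
        return 1.0, table
    _, p = fisher_exact(table, alternative="two-sided")
    return float(p), table


def _write(path: Path, text: str) -> None:
    path.write_text(text, encoding="utf-8")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the output bundle.

    Outputs (in ``config.out_dir``): traits.tsv, edges_type1..4.tsv,
    multiplex.graphml, summary.json, nodes.tsv, complexes.tsv, and — when
    enabled — permutations.tsv, nested_pairs.tsv, regionalization.json,
    plus run.log recording settings and seed.  On error, partial outputs
    are removed and the stage is named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, text: str) -> None:
        p = out / name
        _write(p, text)
        written.append(p)

    try:
        stage = "parse"
        text = Path(config.matrix_path).read_text()
        if config.delimiter is None:
            cm = parse_nexus(text)
        else:
            cm = parse_table(text, delimiter=config.delimiter)

        stage = "recode"
        tm = recode(cm, config.absence_matcher(), min_taxa=config.min_taxa)
        emit("traits.tsv", write_trait_matrix(tm))

        stage = "network"
        net = build_network(tm)
        for i, etype in enumerate(("I", "II", "III", "IV"), start=1):
            emit(f"edges_type{i}.tsv", edge_table(net, etype))
        net.write_graphml(out / "multiplex.graphml")
        written.append(out / "multiplex.graphml")

        stage = "metrics"
        report = summarize(net)
        summary = report.to_dict()

        stage = "phylo"
        tree = None
        if config.tree_path is not None:
            tree = parse_newick(Path(config.tree_path).read_text())
            tree.check_taxa(tm.taxa)
            counts, rows = classify_nested_pairs(net, tree)
            summary["nested_pair_classes"] = counts
            lines = ["inner_node\touter_node\tinner_mono\touter_mono\tclass"]
            lines += [
                f"{a}\t{b}\t{int(mi)}\t{int(mo)}\t{cls}"
                for a, b, mi, mo, cls in rows
            ]
            emit("nested_pairs.tsv", "\n".join(lines) + "\n")

        stage = "nulls"
        stable: set[int] = set()
        pivotal: set[int] = set()
        if config.M > 0:
            scalar_stats = dict(STANDARD_STATISTICS)
            check_permutation_count(config.M, len(scalar_stats), config.alpha)
            check_permutation_count(config.M, tm.N, config.alpha)
            all_stats = {**scalar_stats, **NODE_STATISTICS}
            nulls_e = null_distribution(
                cm, "equiprobable", config.M, all_stats, config.seed,
                absence_matcher=config.absence_matcher(), min_taxa=config.min_taxa,
            )
            nulls_p = None
            if tree is not None:
                w = patristic_weights(tree, cm.taxa, config.k)
                nulls_p = null_distribution(
                    cm, "phylogenetic", config.M, all_stats, config.seed + 1,
                    absence_matcher=config.absence_matcher(),
                    min_taxa=config.min_taxa, weights=w,
                )
            lines = [
                "statistic\tmodel\tobserved\tM\tp_high\tp_low\tp_corrected\tdirection"
            ]
            n_family = len(scalar_stats)
            for name in scalar_stats:
                for nulls in (nulls_e, nulls_p):
                    if nulls is None:
                        continue
                    r = nulls[name]
                    p = min(r.p_high, r.p_low)
                    lines.append(
                        f"{name}\t{r.model}\t{r.observed}\t{r.M_eff}\t"
                        f"{r.p_high}\t{r.p_low}\t{bonferroni(p, n_family)}\t"
                        f"{r.direction(config.alpha, n_family)}"
                    )
            emit("permutations.tsv", "\n".join(lines) + "\n")
            if nulls_p is not None:
                stable = significant_stable_traits(
                    report.degrees, nulls_e["in_degree_II"],
                    nulls_p["in_degree_II"], config.alpha,
                )
                pivotal = significant_pivotal_traits(
                    report.triplets, nulls_e["d_centrality"],
                    nulls_p["d_centrality"], config.alpha,
                )
                summary["n_significantly_stable"] = len(stable)
                summary["n_significantly_pivotal"] = len(pivotal)

        stage = "regionalization"
        if config.regions_path is not None:
            region_map = load_region_map(Path(config.regions_path).read_text())
            p, table = fisher_regionalization(
                region_map, report.degrees, config.region_split
            )
            summary["regionalization"] = {
                "p_two_sided": p,
                "table": table.tolist(),
                "groups": [list(g) for g in config.region_split],
            }
            emit(
                "regionalization.json",
                json.dumps(summary["regionalization"], indent=2) + "\n",
            )

        stage = "report"
        lines = ["node_id\tcharacter_id\tstate_symbol\tlabel\tsupport_size"
                 "\tin_degree_II\tout_degree_II\tflag\td_centrality"
                 "\tsignificantly_stable\tsignificantly_pivotal"]
        for tr, dr, tp in zip(tm.traits, report.degrees, report.triplets):
            lines.append(
                f"{tr.node_id}\t{tr.character_id}\t{tr.state_symbol}\t{tr.label}"
                f"\t{len(tr.support)}\t{dr.in_degree}\t{dr.out_degree}\t{dr.flag}"
                f"\t{tp.d_centrality}\t{int(tr.node_id in stable)}"
                f"\t{int(tr.node_id in pivotal)}"
            )
        emit("nodes.tsv", "\n".join(lines) + "\n")
        lines = ["complex_id\tmember_node_ids\tshared_support"]
        for i, members in enumerate(report.complex_members, start=1):
            sup = sorted(tm.traits[members[0] - 1].support)
            lines.append(f"{i}\t{','.join(map(str, members))}\t{','.join(sup)}")
        emit("complexes.tsv", "\n".join(lines) + "\n")
        emit("summary.json", json.dumps(summary, indent=2, sort_keys=True) + "\n")
        emit(
            "run.log",
            "\n".join(
                f"{k}={getattr(config, k)}"
                for k in (
                    "matrix_path", "tree_path", "regions_path", "min_taxa",
                    "M", "k", "alpha", "seed",
                )
            )
            + "\n",
        )
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return summary
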