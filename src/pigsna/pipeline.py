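"""End-to-end orchestration: simulate/ingest -> networks -> traits -> stats.

The pipeline runs per pen and period: window/posture filtering, bout
detection, pen-day mean-duration thresholding, daily weighted networks,
group and individual traits, Louvain communities, maximal cliques and
co-membership, Mantel comparisons between days and periods, and the
mixed-model period contrast.  A :class:`RunManifest` records the config,
seed, input digests and per-stage counts so a run can be reproduced and
audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import network_metrics, period_comparison, proximity, subgroup_analysis
from .synthetic_data import SimConfig, simulate_pen
from .tracking_io import AnalysisConfig, PenRoster, filter_window, write_tracking
from .validation import validation_report

logger = logging.getLogger(__name__)

PERIODS = ("early", "late")


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True,
                      default=str)
        return path


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, offset: int) -> int:
    return int((seed * 1000 + offset) % (2**31 - 1))


def simulate_period(sim: SimConfig, period: str, seed: int):
    """One period's records+truth; late period gets an offset substream."""
    offset = PERIODS.index(period) if period in PERIODS else 0
    cfg = dataclasses.replace(sim, rng_seed=_stage_seed(seed, offset))
    return simulate_pen(cfg)


def analyse_pen_period(
    records: pd.DataFrame,
    roster: PenRoster,
    config: AnalysisConfig,
    period: str,
    seed: int = 0,
):
    """Analyse one pen-period: networks, traits, subgroups, co-membership.

    Returns a dict with the per-day networks, trait tables, partitions,
    clique sets, co-membership matrices, the per-day subgroup summary table,
    and bout tables.
    """
    filtered = filter_window(records, config)
    nets, raw, qual = proximity.daily_networks(filtered, roster, config, period)
    traits = []
    partitions: dict[int, subgroup_analysis.Partition] = {}
    cliques: dict[int, subgroup_analysis.CliqueSet] = {}
    com: dict[int, pd.DataFrame] = {}
    day_rows = []
    for day, net in sorted(nets.items()):
        part = subgroup_analysis.louvain_partition(net, seed=_stage_seed(seed, day))
        partitions[day] = part
        cs = subgroup_analysis.maximal_cliques(net, config.min_clique_size)
        cliques[day] = cs
        com[day] = subgroup_analysis.co_membership(cs, roster)
        traits.append(network_metrics.group_traits(net, part.labels))
        traits.append(network_metrics.individual_traits(net))
        day_rows.append(
            {
                "pen_id": roster.pen_id,
                "period": period,
                "day": day,
                "n_communities": part.n_communities,
                "n_maximal_cliques": cs.count,
                "largest_clique_size": cs.largest_size,
            }
        )
    return {
        "filtered": filtered,
        "networks": nets,
        "raw_bouts": raw,
        "qualifying_bouts": qual,
        "traits": pd.concat(traits, ignore_index=True) if traits else pd.DataFrame(),
        "partitions": partitions,
        "cliques": cliques,
        "co_membership": com,
        "per_day": pd.DataFrame(day_rows),
    }


def mantel_between_days(
    com: dict[int, pd.DataFrame],
    config: AnalysisConfig,
    seed: int = 0,
    pen_id: str = "",
    period: str = "",
) -> pd.DataFrame:
    """Mantel tests between all day pairs of one pen-period."""
    rows = []
    for (d1, m1), (d2, m2) in itertools.combinations(sorted(com.items()), 2):
        res = subgroup_analysis.mantel_test(
            m1.to_numpy(), m2.to_numpy(),
            n_permutations=config.mantel_permutations,
            seed=_stage_seed(seed, 100 + 10 * d1 + d2),
        )
        rows.append({"pen_id": pen_id, "period": period, "day_a": d1, "day_b": d2,
                     "r": res.r, "p": res.p, "flagged": res.flagged})
    return pd.DataFrame(rows)


def mantel_between_periods(
    com_early: dict[int, pd.DataFrame],
    com_late: dict[int, pd.DataFrame],
    config: AnalysisConfig,
    seed: int = 0,
    pen_id: str = "",
) -> pd.DataFrame:
    """Cross-period Mantel tests: matched day pairs and all cross pairs."""
    rows = []
    e_days, l_days = sorted(com_early), sorted(com_late)
    for k, (d1, d2) in enumerate(itertools.product(e_days, l_days)):
        res = subgroup_analysis.mantel_test(
            com_early[d1].to_numpy(), com_late[d2].to_numpy(),
            n_permutations=config.mantel_permutations,
            seed=_stage_seed(seed, 500 + k),
        )
        matched = (e_days.index(d1) == l_days.index(d2))
        rows.append({"pen_id": pen_id, "day_early": d1, "day_late": d2,
                     "matched": matched, "r": res.r, "p": res.p,
                     "flagged": res.flagged})
    return pd.DataFrame(rows)


def export_networks(nets: dict[int, proximity.ContactNetwork], outdir: Path,
                    prefix: str) -> list[Path]:
    """Write each daily network as GraphML plus a weighted edge-list CSV."""
    paths = []
    for day, net in sorted(nets.items()):
        gml = outdir / f"{prefix}_day{day}.graphml"
        nx.write_graphml(net.graph, gml)
        edges = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in net.graph.edges(data=True)],
            columns=["animal_a", "animal_b", "weight_s"],
        ).sort_values(["animal_a", "animal_b"])
        csv = outdir / f"{prefix}_day{day}_edges.csv"
        edges.to_csv(csv, index=False)
        paths += [gml, csv]
    return paths


def run_pipeline(
    sim: SimConfig,
    config: AnalysisConfig,
    outdir,
    seed: int = 0,
    n_pens: int = 1,
    input_csvs: dict | None = None,
) -> RunManifest:
    """Run the full analysis over ``n_pens`` simulated pens and two periods.

    If ``input_csvs`` maps (pen_id, period) -> tracking CSV path, those files
    are ingested instead of simulating.  All outputs are written under
    ``outdir``; returns the run manifest (also written as manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={"analysis": config.to_dict(),
                "simulation": dataclasses.asdict(sim)},
        seed=int(seed),
    )
    all_traits = []
    all_per_day = []
    mantel_rows = []
    pen_sizes = {}
    from .tracking_io import read_tracking

    for p in range(n_pens):
        pen_id = f"pen{p + 1}"
        pen_sim = dataclasses.replace(sim, pen_id=pen_id,
                                      rng_seed=_stage_seed(seed, 7 * p))
        roster = pen_sim.roster()
        pen_sizes[pen_id] = roster.n
        com_by_period = {}
        for period in PERIODS:
            key = f"{pen_id}_{period}"
            if input_csvs and (pen_id, period) in input_csvs:
                path = input_csvs[(pen_id, period)]
                records = read_tracking(path, roster, config.coordinate_tolerance_m)
                manifest.input_digests[str(path)] = _digest(path)
            else:
                records, _truth = simulate_period(
                    pen_sim, period, _stage_seed(seed, 7 * p))
                path = outdir / f"tracking_{key}.csv"
                write_tracking(records, path)
                manifest.outputs.append(str(path))
            res = analyse_pen_period(records, roster, config, period,
                                     seed=_stage_seed(seed, 7 * p + 3))
            vr = validation_report(records, roster)
            vr.to_csv(outdir / f"validation_{key}.csv", index=False)
            res["raw_bouts"].to_csv(outdir / f"bouts_raw_{key}.csv", index=False)
            res["qualifying_bouts"].to_csv(outdir / f"bouts_qualifying_{key}.csv",
                                           index=False)
            export_networks(res["networks"], outdir, f"network_{key}")
            for day, m in res["co_membership"].items():
                m.to_csv(outdir / f"comembership_{key}_day{day}.csv")
            parts = pd.DataFrame(
                [(day, a, c) for day, part in res["partitions"].items()
                 for a, c in sorted(part.labels.items())],
                columns=["day", "animal_id", "community"],
            )
            parts.to_csv(outdir / f"communities_{key}.csv", index=False)
            cl = pd.DataFrame(
                [(day, "|".join(c)) for day, cs in res["cliques"].items()
                 for c in cs.cliques],
                columns=["day", "clique"],
            )
            cl.to_csv(outdir / f"cliques_{key}.csv", index=False)
            all_traits.append(res["traits"])
            all_per_day.append(res["per_day"])
            com_by_period[period] = res["co_membership"]
            manifest.stage_counts[key] = {
                "records": int(len(records)),
                "filtered": int(len(res["filtered"])),
                "raw_bouts": int(len(res["raw_bouts"])),
                "qualifying_bouts": int(len(res["qualifying_bouts"])),
                "qualifying_seconds": float(res["qualifying_bouts"]["duration_s"].sum())
                if len(res["qualifying_bouts"]) else 0.0,
                "network_weight_s": float(sum(
                    net.total_weight() for net in res["networks"].values())),
            }
            mantel_rows.append(
                mantel_between_days(res["co_membership"], config,
                                    seed=_stage_seed(seed, 7 * p + 5),
                                    pen_id=pen_id, period=period)
            )
        mantel_rows.append(
            mantel_between_periods(com_by_period["early"], com_by_period["late"],
                                   config, seed=_stage_seed(seed, 7 * p + 6),
                                   pen_id=pen_id)
        )

    traits = pd.concat(all_traits, ignore_index=True)
    traits.to_csv(outdir / "traits.csv", index=False)
    network_metrics.summarize_traits(traits).to_csv(
        outdir / "traits_summary.csv", index=False)
    per_day = pd.concat(all_per_day, ignore_index=True)
    per_day.to_csv(outdir / "subgroups_per_day.csv", index=False)
    subgroup_analysis.summarize_subgroups(per_day).to_csv(
        outdir / "subgroups_summary.csv", index=False)
    mantel = pd.concat(mantel_rows, ignore_index=True)
    mantel.to_csv(outdir / "mantel.csv", index=False)

    if n_pens >= 2:
        group = traits[traits["level"] == "group"]
        sub_long = per_day.melt(
            id_vars=["pen_id", "period", "day"],
            value_vars=["n_communities", "n_maximal_cliques", "largest_clique_size"],
            var_name="trait", value_name="value")
        model_input = pd.concat([group, sub_long], ignore_index=True)
        comparison = period_comparison.compare_all(model_input, pen_sizes)
        comparison.to_csv(outdir / "period_comparison.csv", index=False)
        manifest.outputs.append(str(outdir / "period_comparison.csv"))

    manifest.outputs += [str(outdir / f) for f in
                         ("traits.csv", "traits_summary.csv",
                          "subgroups_per_day.csv", "subgroups_summary.csv",
                          "mantel.csv")]
    manifest.to_json(outdir / "manifest.json")
    return manifest
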