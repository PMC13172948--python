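"""Signal ranking, SOC shares, sector-map matrices and the pipeline driver.

The screening output of :mod:`cdpsignal.disproportionality` is turned
into the analyst-facing artefacts: top-k signal listings ranked by the
IC credible lower bound (IC_025), per-SOC shares of flagged signals, and
paired sector-map matrices that place the same PT in the same cell for
two exposure groups so their signal profiles can be compared visually.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .descriptives import demographic_table
from .disproportionality import ScreenConfig, screen_all, stratify_by_indication
from .exposure import assign_groups, find_candidate_terms, summarize_inventory
from .faers_io import ReportSet, read_bundles, restrict_period


def rank_signals(signals: pd.DataFrame, k: int, key: str = "ic_lo") -> pd.DataFrame:
    """Top-k IC-flagged signals by *key* (default IC_025), descending.

    Unflagged estimates are excluded; ties break deterministically by
    (a descending, PT ascending).
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    flagged = signals[signals["flag_ic"]].copy()
    flagged = flagged.sort_values(
        by=[key, "a", "pt"], ascending=[False, False, True], kind="mergesort"
    )
    return flagged.head(k).reset_index(drop=True)


def soc_share(signals: pd.DataFrame) -> pd.DataFrame:
    """Percentage of IC-flagged signals falling in each SOC."""
    flagged = signals[signals["flag_ic"]]
    if flagged.empty:
        return pd.DataFrame(columns=["soc", "n_flagged", "pct"])
    counts = flagged["soc"].value_counts()
    return pd.DataFrame(
        {
            "soc": counts.index,
            "n_flagged": counts.values,
            "pct": 100.0 * counts.values / counts.sum(),
        }
    ).reset_index(drop=True)


@dataclass
class SectorMapMatrix:
    """Aligned IC_025 grids for two exposure groups over one SOC.

    ``values`` holds IC_025 per PT per group; NaN distinguishes *absent*
    (PT never observed for that group) from a negative IC_025 (observed,
    no signal).  PT order is alphabetical by PT name and identical for
    both groups, so cell positions are comparable across the two grids.
    """

    soc: str
    pts: list[str]
    pt_names: list[str]
    groups: tuple[str, str]
    values: pd.DataFrame  # index pt, one column per group, IC_025 or NaN
    n_rows: int = field(init=False)
    n_cols: int = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.pts)
        self.n_cols = max(1, math.ceil(math.sqrt(n)))
        self.n_rows = max(1, math.ceil(n / self.n_cols))

    def bright_count(self, group: str) -> int:
        """Cells with IC_025 > 0 for *group* (the flagged signals)."""
        col = self.values[group]
        return int((col > 0).sum())

    def grid(self, group: str) -> np.ndarray:
        """Row-major matrix of IC_025 values padded with NaN."""
        out = np.full(self.n_rows * self.n_cols, np.nan)
        out[: len(self.pts)] = self.values[group].to_numpy()
        return out.reshape(self.n_rows, self.n_cols)

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "pt_name", self.pt_names)
        df.index.name = "pt"
        return df.reset_index()


def sector_map(
    signals_g1: pd.DataFrame, signals_g2: pd.DataFrame, soc: str
) -> SectorMapMatrix:
    """Build the paired sector-map matrix for one SOC.

    The PT universe is the union of the SOC's PTs appearing in either
    group's screening; both screenings must use the same PT->SOC lookup.
    """
    g1 = signals_g1["group"].iloc[0] if len(signals_g1) else "group1"
    g2 = signals_g2["group"].iloc[0] if len(signals_g2) else "group2"
    s1 = signals_g1[signals_g1["soc"] == soc].set_index("pt")
    s2 = signals_g2[signals_g2["soc"] == soc].set_index("pt")
    if s1.empty and s2.empty:
        raise ValueError(f"SOC {soc!r} absent from both screenings")
    names = pd.concat([s1["pt_name"], s2["pt_name"]])
    names = names[~names.index.duplicated()]
    order = names.sort_values(kind="mergesort").index.tolist()
    values = pd.DataFrame(
        {
            g1: s1["ic_lo"].reindex(order),
            g2: s2["ic_lo"].reindex(order),
        },
        index=pd.Index(order, name="pt"),
    )
    return SectorMapMatrix(
        soc=soc,
        pts=order,
        pt_names=names.loc[order].tolist(),
        groups=(g1, g2),
        values=values,
    )


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Execute simulate/ingest -> map -> describe -> screen -> report.

    ``config`` keys:

    - ``simulate``: generator options (n_reports, seed, ...) — mutually
      exclusive with ``bundles`` (a directory plus quarter list);
    - ``mapping``: path to the curated term-mapping table (optional when
      simulating: the generator's truth mapping is used);
    - ``window``: [start, end] quarters for the disproportionality step;
    - ``groups``: exposure groups to screen (default: all assigned);
    - ``screen``: ScreenConfig fields; ``rank_k`` (default 15);
    - ``sector_soc`` plus two groups for the paired sector map (optional).

    Every artefact lands under *out_dir*; the run manifest records the
    config hash, seed and package version so identical configurations
    reproduce identical artefacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"out_dir": str(out)}

    stage = "input"
    try:
        if "simulate" in config:
            from .simulate import GeneratorConfig, PlantedSignal, make_vocabulary, sample_reports

            sim = dict(config["simulate"])
            planted = tuple(
                PlantedSignal(**p) for p in sim.pop("planted_signals", [])
            )
            gen = GeneratorConfig(**sim, planted_signals=planted)
            vocab = make_vocabulary(gen)
            rs, truth = sample_reports(gen, vocab)
            truth.write(out)
            pt_soc = vocab.pt_soc_lookup()
            pt_names = vocab.pt_name_lookup()
            mapping = (
                truth.mapping_table()
                if "mapping" not in config
                else _load_mapping(config["mapping"])
            )
        elif "bundles" in config:
            from .exposure import load_mapping_table

            if "mapping" not in config:
                stage = "map"
                raise ValueError(
                    "config must name a term-mapping table when ingesting bundles"
                )
            b = config["bundles"]
            rs = read_bundles(b["dir"], b["quarters"])
            mapping = load_mapping_table(config["mapping"])
            pt_soc = _load_pt_soc(config.get("pt_soc"))
            pt_names = {}
        else:
            raise ValueError("config must contain either 'simulate' or 'bundles'")

        stage = "map"
        inventory = find_candidate_terms(rs)
        inventory.table.to_csv(out / "term_inventory.tsv", sep="\t", index=False)
        assignment = assign_groups(rs, mapping, strict=bool(config.get("strict", False)))
        if assignment.review_terms:
            (out / "terms_to_review.txt").write_text(
                "\n".join(assignment.review_terms) + "\n"
            )
        summarize_inventory(mapping).to_csv(out / "inventory_summary.tsv", sep="\t", index=False)

        stage = "describe"
        table1 = demographic_table(rs, assignment)
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)

        stage = "screen"
        window = config.get("window")
        rs_window = restrict_period(rs, *window) if window else rs
        groups = config.get("groups") or sorted(assignment.case_groups["group"].unique())
        screen_cfg = ScreenConfig(**config.get("screen", {}))
        rank_k = int(config.get("rank_k", 15))
        signal_tables = {}
        for g in groups:
            sig = screen_all(rs_window, assignment, g, pt_soc, screen_cfg, pt_names)
            safe = g.replace("/", "-").replace(" ", "_").lower()
            sig.to_csv(out / f"signals_{safe}.tsv", sep="\t", index=False)
            rank_signals(sig, rank_k).to_csv(
                out / f"top_signals_{safe}.tsv", sep="\t", index=False
            )
            soc_share(sig).to_csv(out / f"soc_share_{safe}.tsv", sep="\t", index=False)
            signal_tables[g] = sig

        stage = "report"
        if "sector_soc" in config:
            g1, g2 = config.get("sector_groups", groups[:2])
            sm = sector_map(signal_tables[g1], signal_tables[g2], config["sector_soc"])
            sm.to_frame().to_csv(out / "sector_map.tsv", sep="\t", index=False)
            artifacts["sector_bright"] = {
                g1: sm.bright_count(g1), g2: sm.bright_count(g2)
            }
    except Exception as err:  # annotate with the failing stage, then re-raise
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "config_hash": _config_hash(dict(config)),
        "seed": config.get("simulate", {}).get("seed"),
        "version": __version__,
        "n_reports": int(len(rs)),
        "groups": list(groups),
    }
    (out / "pipeline_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts.update(manifest)
    artifacts["signals"] = signal_tables
    artifacts["table1"] = table1
    return artifacts


def _load_mapping(mapping) -> pd.DataFrame:
    from .exposure import load_mapping_table, validate_mapping

    if isinstance(mapping, (str, Path)):
        return load_mapping_table(mapping)
    return validate_mapping(mapping)


def _load_pt_soc(path) -> dict[str, str]:
    if path is None:
        return {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
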