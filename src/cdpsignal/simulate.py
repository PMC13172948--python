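"""Synthetic FAERS-dialect spontaneous-report bundles with known truth.

The generator emulates the features of real spontaneous-report data that
the analysis pipeline must survive: case versioning and duplication
across quarters, messy cannabis-derived-product (CDP) nomenclature
(misspellings and brand/chemical/informal variants), demographic and
role distributions that differ by exposure group, indication-linked
event reporting, and planted drug-event pairs with specified
reporting-rate ratios over an independent background.

Event model: within a report of exposure group g, preferred term (PT) e
occurs independently with probability min(1, pi_e * rho_{g,e}), where
pi_e is the background PT probability and rho comes from a
:class:`PlantedSignal` (rho = 1 for unplanted pairs).  All randomness
flows from one root seed through named substreams, so partial artefacts
are reproducible in isolation and identical configurations yield
byte-identical bundles.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._quarters import quarter_range, quarter_start_date
from .exposure import GROUPS, QUERY_STRINGS, matching_queries, normalize_term
from .faers_io import AGE_UNIT_FACTORS, COLUMNS, ReportSet, TABLES

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSignal:
    """Simulation truth for one group x PT pair.

    ``rho`` multiplies the background PT probability within reports of
    the group; ``rho = 1`` is a null pair.  With ``indication_linked``
    the multiplier applies only to reports whose CDP mention carries the
    seizure-like indication, which lets subgroup analyses be exercised.
    """

    group: str
    pt: str
    rho: float
    indication_linked: bool = False

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")


#: default report-share of each exposure group (remainder = non-CDP
#: background reports); loosely proportioned like the published FAERS
#: report counts per group
DEFAULT_GROUP_WEIGHTS: Mapping[str, float] = {
    "Epidiolex": 0.065,
    "Rx THC": 0.040,
    "Sativex": 0.004,
    "THC": 0.008,
    "THC/CBD": 0.002,
    "CBD": 0.020,
    "Cannabis": 0.070,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one simulated reporting universe."""

    n_reports: int = 50_000
    quarters: tuple[str, ...] = tuple(quarter_range("2018Q2", "2023Q1"))
    n_background_drugs: int = 40
    n_pts: int = 100
    n_socs: int = 6
    cdp_group_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    planted_signals: tuple[PlantedSignal, ...] = ()
    duplicate_rate: float = 0.10
    missing_age_rate: float = 0.30
    missing_sex_rate: float = 0.10
    misspelling_rate: float = 0.15
    #: per-group probability that the CDP mention carries the seizure-like
    #: indication PT
    indication_rates: Mapping[str, float] = field(
        default_factory=lambda: {"Epidiolex": 0.85, "CBD": 0.10}
    )
    background_indication_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_reports", "n_background_drugs", "n_pts", "n_socs"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_socs > self.n_pts:
            raise ValueError("n_socs must not exceed n_pts")
        if not self.quarters:
            raise ValueError("quarters must be non-empty")
        from ._quarters import quarter_index

        idx = [quarter_index(q) for q in self.quarters]
        if idx != sorted(idx):
            raise ValueError("quarters must be ordered")
        for name in (
            "duplicate_rate", "missing_age_rate", "missing_sex_rate",
            "misspelling_rate", "background_indication_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = 0.0
        for g, w in self.cdp_group_weights.items():
            if g not in GROUPS:
                raise ValueError(f"cdp_group_weights: unknown group {g!r}")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"cdp_group_weights[{g!r}] must lie in [0, 1]")
            total += w
        if total > 1.0 + 1e-12:
            raise ValueError(f"cdp_group_weights sum to {total:.4f} > 1")
        for g, r in self.indication_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"indication_rates[{g!r}] must lie in [0, 1]")
        for ps in self.planted_signals:
            if ps.group not in GROUPS:
                raise ValueError(f"planted signal references unknown group {ps.group!r}")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream off the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

#: canonical verbatim CDP terms per group; every term contains at least
#: one query substring after lowercasing (the EU brand spelling carries
#: its active ingredient parenthetically so the chemical-name query
#: anchors it)
CDP_TERM_POOLS: Mapping[str, tuple[str, ...]] = {
    "Epidiolex": ("EPIDIOLEX", "EPIDYOLEX (CANNABIDIOL)"),
    "Rx THC": ("DRONABINOL", "MARINOL", "SYNDROS", "NABILONE", "CESAMET"),
    "Sativex": ("SATIVEX", "NABIXIMOLS"),
    "THC": (
        "TETRAHYDROCANNABINOL",
        "DELTA-9-TETRAHYDROCANNABINOL",
        "DELTA-8-THC",
        "THC OIL",
    ),
    "THC/CBD": ("THC/CBD", "THC:CBD OIL"),
    "CBD": ("CANNABIDIOL", "CBD OIL", "CBD GUMMIES", "HEMP-DERIVED CBD EXTRACT"),
    "Cannabis": (
        "CANNABIS",
        "MARIJUANA",
        "MARIHUANA",
        "CANNABIS SATIVA EXTRACT",
        "MEDICAL MARIJUANA",
    ),
}

_SEIZURE_PT_NAMES = (
    "Seizure", "Seizure cluster", "Convulsion", "Status epilepticus",
    "Somnolence", "Dizziness", "Tremor", "Ataxia",
)
_GENERAL_PT_NAMES = (
    "Nausea", "Vomiting", "Diarrhoea", "Rash", "Fatigue",
    "Hepatic enzyme increased", "Weight decreased", "Headache",
    "Pruritus", "Pyrexia",
)
_INDICATION_PT_NAMES = ("Epilepsy", "Chronic pain", "Anxiety disorder", "Sleep disorder")
SEIZURE_INDICATION_NAME = "Epilepsy"

_SOC_NAMES = (
    "Nervous system disorders",
    "Psychiatric disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Investigations",
    "Skin and subcutaneous tissue disorders",
)


@dataclass
class Vocabulary:
    """Drug names, CDP term pools, the PT/SOC table and PT frequencies."""

    drug_names: tuple[str, ...]
    cdp_term_pools: Mapping[str, tuple[str, ...]]
    pt_table: pd.DataFrame  # pt_id, pt_name, soc_id, soc_name, background_prob
    indication_pts: tuple[str, ...]

    @property
    def pt_ids(self) -> np.ndarray:
        return self.pt_table["pt_id"].to_numpy()

    @property
    def background_probs(self) -> np.ndarray:
        return self.pt_table["background_prob"].to_numpy()

    def pt_soc_lookup(self) -> dict[str, str]:
        return dict(zip(self.pt_table["pt_id"], self.pt_table["soc_id"]))

    def pt_name_lookup(self) -> dict[str, str]:
        return dict(zip(self.pt_table["pt_id"], self.pt_table["pt_name"]))

    def pt_by_name(self, name: str) -> str:
        hit = self.pt_table.loc[self.pt_table["pt_name"] == name, "pt_id"]
        if hit.empty:
            raise KeyError(f"no PT named {name!r}")
        return hit.iloc[0]

    @property
    def seizure_indication_pt(self) -> str:
        return self.pt_by_name(SEIZURE_INDICATION_NAME)

    def seizure_pts(self) -> list[str]:
        names = set(_SEIZURE_PT_NAMES[:4])  # the convulsive-event terms
        sub = self.pt_table[self.pt_table["pt_name"].isin(names)]
        return list(sub["pt_id"])


def make_vocabulary(config: GeneratorConfig) -> Vocabulary:
    """Deterministic vocabulary for the configured sizes and seed."""
    config.validate()
    n_pts, n_socs = config.n_pts, config.n_socs

    suffixes = ("", " TABLETS", " CAPSULES", " INJECTION")
    drug_names = tuple(
        f"COMPOUND {i:03d}{suffixes[i % len(suffixes)]}"
        for i in range(config.n_background_drugs)
    )
    for name in drug_names:
        if matching_queries(name):
            raise ValueError(f"background drug name {name!r} collides with a CDP query")

    pt_ids = [f"PT{i:04d}" for i in range(n_pts)]
    pt_names = [f"Event term {i:04d}" for i in range(n_pts)]
    used: set[int] = set()
    # convulsive/neurological terms pinned to SOC 0 (indices = 0 mod n_socs)
    for j, name in enumerate(_SEIZURE_PT_NAMES):
        i = j * n_socs
        if i >= n_pts:
            break
        pt_names[i] = name
        used.add(i)
    free = (i for i in range(n_pts) if i not in used)
    for name in _INDICATION_PT_NAMES + _GENERAL_PT_NAMES:
        try:
            i = next(free)
        except StopIteration:
            break
        pt_names[i] = name
        used.add(i)

    soc_ids = [f"SOC{i % n_socs:02d}" for i in range(n_pts)]
    soc_names = [
        _SOC_NAMES[j] if j < len(_SOC_NAMES) else f"System organ class {j:02d}"
        for j in range(n_socs)
    ]

    rng = _rng(config.seed, "vocabulary")
    # log-spaced background PT rates: a few common events and a long rare
    # tail, the shape real PT frequency spectra take
    probs = np.logspace(np.log10(3e-5), np.log10(0.04), n_pts)
    rng.shuffle(probs)
    # keep the convulsive-event PTs common enough to be plantable
    for j in range(len(_SEIZURE_PT_NAMES)):
        i = j * n_socs
        if i < n_pts:
            probs[i] = max(probs[i], 0.004)

    pt_table = pd.DataFrame(
        {
            "pt_id": pt_ids,
            "pt_name": pt_names,
            "soc_id": soc_ids,
            "soc_name": [soc_names[int(s[3:])] for s in soc_ids],
            "background_prob": probs,
        }
    )
    name_to_id = dict(zip(pt_table["pt_name"], pt_table["pt_id"]))
    indication_pts = tuple(
        name_to_id[n] for n in _INDICATION_PT_NAMES if n in name_to_id
    )
    if SEIZURE_INDICATION_NAME not in name_to_id:
        raise ValueError(
            f"n_pts={n_pts} too small to host the seizure-like indication PT"
        )
    for group, pool in CDP_TERM_POOLS.items():
        for term in pool:
            if not matching_queries(term):
                raise ValueError(f"pool term {term!r} for {group} matches no query")
    return Vocabulary(
        drug_names=drug_names,
        cdp_term_pools={g: tuple(p) for g, p in CDP_TERM_POOLS.items()},
        pt_table=pt_table,
        indication_pts=indication_pts,
    )


# ---------------------------------------------------------------------------
# term perturbation
# ---------------------------------------------------------------------------

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def perturb_term(term: str, seed: int) -> str:
    """Single-character misspelling that keeps the term discoverable.

    The first matched query substring is treated as the term's anchor and
    is never edited, so the variant still matches the query list.  When no
    character outside the anchor can be edited safely the term is returned
    unchanged.
    """
    if not term:
        raise ValueError("term must be non-empty")
    hits = matching_queries(term)
    if not hits:
        return term
    anchor = hits[0]
    start = term.lower().index(anchor)
    end = start + len(anchor)
    positions = [i for i in range(len(term)) if not (start <= i < end)]
    if not positions:
        return term
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    pos = int(positions[rng.integers(len(positions))])
    op = rng.integers(4)
    if op == 0:  # substitution
        repl = _LETTERS[rng.integers(len(_LETTERS))]
        while repl == term[pos].upper():
            repl = _LETTERS[rng.integers(len(_LETTERS))]
        return term[:pos] + repl + term[pos + 1 :]
    if op == 1:  # deletion
        return term[:pos] + term[pos + 1 :]
    if op == 2:  # insertion (after pos, never inside the anchor span)
        at = pos if pos < start else pos + 1
        repl = _LETTERS[rng.integers(len(_LETTERS))]
        return term[:at] + repl + term[at:]
    # transposition with a neighbour also outside the anchor
    nxt = pos + 1
    if nxt < len(term) and nxt in positions:
        return term[:pos] + term[nxt] + term[pos] + term[nxt + 1 :]
    prv = pos - 1
    if prv >= 0 and prv in positions:
        return term[:prv] + term[pos] + term[prv] + term[pos + 1 :]
    return term


# ---------------------------------------------------------------------------
# report sampling
# ---------------------------------------------------------------------------

#: per-group reporting profiles (age location/scale in years, probability
#: of female sex, role distribution of the CDP mention, country mix);
#: shaped after the qualitative contrasts of real CDP reporting — the
#: pharmaceutical CBD group is paediatric and primary-suspect-heavy, the
#: herbal groups skew to adult males in secondary-suspect/concomitant
#: roles — without calibrating to any external counts
GROUP_PROFILES: Mapping[str, dict] = {
    "Epidiolex": dict(age=(10.0, 8.0), p_female=0.45,
                      roles=(0.90, 0.04, 0.01, 0.05),
                      countries=(("US", 0.95), ("CA", 0.01), ("DE", 0.02), ("JP", 0.02))),
    "Rx THC": dict(age=(55.0, 15.0), p_female=0.50,
                   roles=(0.10, 0.08, 0.01, 0.81),
                   countries=(("US", 0.72), ("CA", 0.17), ("DE", 0.08), ("JP", 0.03))),
    "Sativex": dict(age=(48.0, 12.0), p_female=0.64,
                    roles=(0.02, 0.11, 0.01, 0.86),
                    countries=(("GB", 0.55), ("DE", 0.38), ("CA", 0.04), ("US", 0.03))),
    "THC": dict(age=(28.0, 10.0), p_female=0.37,
                roles=(0.24, 0.51, 0.04, 0.21),
                countries=(("US", 0.57), ("CA", 0.05), ("DE", 0.25), ("JP", 0.13))),
    "THC/CBD": dict(age=(42.0, 15.0), p_female=0.54,
                    roles=(0.48, 0.13, 0.05, 0.34),
                    countries=(("US", 0.73), ("CA", 0.16), ("DE", 0.10), ("JP", 0.01))),
    "CBD": dict(age=(50.0, 20.0), p_female=0.55,
                roles=(0.09, 0.16, 0.04, 0.71),
                countries=(("US", 0.62), ("CA", 0.20), ("DE", 0.15), ("JP", 0.03))),
    "Cannabis": dict(age=(32.0, 13.0), p_female=0.38,
                     roles=(0.01, 0.52, 0.01, 0.46),
                     countries=(("US", 0.52), ("CA", 0.16), ("DE", 0.26), ("JP", 0.06))),
}
_BACKGROUND_PROFILE = dict(
    age=(52.0, 18.0), p_female=0.55, roles=(0.35, 0.15, 0.02, 0.48),
    countries=(("US", 0.60), ("CA", 0.06), ("DE", 0.20), ("JP", 0.14)),
)

_ROLE_CODES = ("PS", "SS", "I", "C")
#: marginal probability of each serious-outcome code per report
OUTCOME_PROBS: Mapping[str, float] = {
    "HO": 0.30, "OT": 0.45, "DE": 0.10, "LT": 0.035,
    "DS": 0.02, "CA": 0.004, "RI": 0.008,
}
_AGE_UNIT_CHOICES = ("YR", "MON", "DY", "DEC")
_AGE_UNIT_PROBS = (0.91, 0.03, 0.03, 0.03)


@dataclass
class SimulationTruth:
    """Ground truth carried alongside a simulated :class:`ReportSet`."""

    planted: pd.DataFrame          # group, pt, rho, indication_linked
    case_groups: pd.DataFrame      # case_id, group (the true exposure labels)
    term_groups: pd.DataFrame      # verbatim_term (normalized), group
    manifest: dict

    def mapping_table(self) -> pd.DataFrame:
        """Curated-mapping analogue derived from the emitted terms."""
        from .exposure import validate_mapping

        df = self.term_groups.copy()
        df["matched_query"] = [matching_queries(t)[0] for t in df["verbatim_term"]]
        df["note"] = "generator truth"
        return validate_mapping(df)

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        planted_path = out / "planted_truth.tsv"
        self.planted.to_csv(planted_path, sep="\t", index=False)
        manifest_path = out / "run_manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return [planted_path, manifest_path]


def _profile_for(group: str | None) -> dict:
    return GROUP_PROFILES.get(group, _BACKGROUND_PROFILE) if group else _BACKGROUND_PROFILE


def sample_reports(
    config: GeneratorConfig, vocab: Vocabulary
) -> tuple[ReportSet, SimulationTruth]:
    """Draw the full simulated reporting universe.

    Returns the deduplicated final-state :class:`ReportSet` (what a
    correct ingest of the written bundle must reproduce) together with
    the :class:`SimulationTruth`.  The version-level raw tables needed to
    write a quarterly bundle ride along on the report set.
    """
    config.validate()
    n = config.n_reports
    n_pts = config.n_pts
    pt_ids = vocab.pt_ids
    pt_index = {p: i for i, p in enumerate(pt_ids)}
    for ps in config.planted_signals:
        if ps.pt not in pt_index:
            raise ValueError(f"planted signal PT {ps.pt!r} not in vocabulary")

    group_names = [g for g, w in config.cdp_group_weights.items() if w > 0]
    for g in group_names:
        if not vocab.cdp_term_pools.get(g):
            raise ValueError(f"group {g!r} has positive weight but an empty term pool")

    # --- exposure labels ---------------------------------------------------
    w = np.array([config.cdp_group_weights[g] for g in group_names], dtype=float)
    p_all = np.append(w, 1.0 - w.sum())
    glab = _rng(config.seed, "groups").choice(len(group_names) + 1, size=n, p=p_all)
    group_of = np.array(group_names + [None], dtype=object)[glab]

    case_num = 10_000_001 + np.arange(n, dtype=np.int64)
    case_id = case_num.astype(str)

    # --- calendar anchor ---------------------------------------------------
    nq = len(config.quarters)
    init_q_idx = _rng(config.seed, "quarters").integers(0, nq, size=n)

    # --- demographics ------------------------------------------------------
    rng_demo = _rng(config.seed, "demographics")
    age_true = np.empty(n)
    sex_female = np.empty(n, dtype=bool)
    country = np.empty(n, dtype=object)
    for g in group_names + [None]:
        mask = group_of == g if g is not None else pd.isna(pd.Series(group_of)).to_numpy()
        m = int(mask.sum())
        if not m:
            continue
        prof = _profile_for(g)
        mu, sd = prof["age"]
        age_true[mask] = np.clip(rng_demo.normal(mu, sd, size=m), 0.0, 95.0)
        sex_female[mask] = rng_demo.random(m) < prof["p_female"]
        codes, cps = zip(*prof["countries"])
        country[mask] = np.array(codes, dtype=object)[
            rng_demo.choice(len(codes), size=m, p=np.array(cps) / np.sum(cps))
        ]
    age_missing = _rng(config.seed, "missing-age").random(n) < config.missing_age_rate
    sex_missing = _rng(config.seed, "missing-sex").random(n) < config.missing_sex_rate
    country_missing = _rng(config.seed, "missing-country").random(n) < 0.04
    country[country_missing] = None

    unit_idx = _rng(config.seed, "age-units").choice(
        len(_AGE_UNIT_CHOICES), size=n, p=_AGE_UNIT_PROBS
    )
    age_unit = np.array(_AGE_UNIT_CHOICES, dtype=object)[unit_idx]
    factors = np.array([AGE_UNIT_FACTORS[u] for u in _AGE_UNIT_CHOICES])[unit_idx]
    stored_val = np.round(age_true / factors, 1)
    age_stored = np.array([f"{v:.1f}" for v in stored_val], dtype=object)
    age_stored[age_missing] = ""
    age_unit[age_missing] = ""

    # --- drug mentions -----------------------------------------------------
    rng_drug = _rng(config.seed, "drugs")
    n_bg = 1 + np.minimum(rng_drug.poisson(1.2, size=n), 3)
    is_cdp = group_of != None  # noqa: E711  (object-array comparison)
    bg_names = np.array(vocab.drug_names, dtype=object)
    total_bg = int(n_bg.sum())
    bg_pick = bg_names[rng_drug.integers(0, len(bg_names), size=total_bg)]
    bg_roles = np.array(_ROLE_CODES, dtype=object)[
        rng_drug.choice(4, size=total_bg, p=_BACKGROUND_PROFILE["roles"])
    ]

    # CDP mention per exposed report
    rng_term = _rng(config.seed, "terms")
    cdp_rows = np.flatnonzero(is_cdp)
    cdp_term = np.empty(len(cdp_rows), dtype=object)
    cdp_role = np.empty(len(cdp_rows), dtype=object)
    for g in group_names:
        gmask = group_of[cdp_rows] == g
        m = int(gmask.sum())
        if not m:
            continue
        pool = np.array(vocab.cdp_term_pools[g], dtype=object)
        cdp_term[gmask] = pool[rng_term.integers(0, len(pool), size=m)]
        cdp_role[gmask] = np.array(_ROLE_CODES, dtype=object)[
            rng_term.choice(4, size=m, p=GROUP_PROFILES[g]["roles"])
        ]
    misspell = _rng(config.seed, "misspell").random(len(cdp_rows)) < config.misspelling_rate
    pert_seeds = _rng(config.seed, "misspell-seeds").integers(0, 2**31 - 1, size=len(cdp_rows))
    for i in np.flatnonzero(misspell):
        cdp_term[i] = perturb_term(cdp_term[i], int(pert_seeds[i]))

    # assemble the case-level drug table: CDP mention first (seq 1)
    drug_case, drug_seq, drug_name, drug_role = [], [], [], []
    bg_offsets = np.concatenate([[0], np.cumsum(n_bg)])
    cdp_pos = {r: i for i, r in enumerate(cdp_rows)}
    for r in range(n):
        seq = 1
        if r in cdp_pos:
            drug_case.append(case_id[r]); drug_seq.append(str(seq))
            drug_name.append(cdp_term[cdp_pos[r]]); drug_role.append(cdp_role[cdp_pos[r]])
            seq += 1
        for j in range(bg_offsets[r], bg_offsets[r + 1]):
            drug_case.append(case_id[r]); drug_seq.append(str(seq))
            drug_name.append(bg_pick[j]); drug_role.append(bg_roles[j])
            seq += 1
    drugs = pd.DataFrame(
        {"case_id": drug_case, "drug_seq": drug_seq,
         "role": drug_role, "verbatim_name": drug_name}
    )

    # --- indications -------------------------------------------------------
    rng_indi = _rng(config.seed, "indications")
    seiz_pt = vocab.seizure_indication_pt
    cdp_has_ind = np.zeros(n, dtype=bool)
    indi_case, indi_seq, indi_pt = [], [], []
    for g in group_names:
        rate = config.indication_rates.get(g, 0.0)
        rows = np.flatnonzero(group_of == g)
        hit = rng_indi.random(len(rows)) < rate
        for r in rows[hit]:
            cdp_has_ind[r] = True
            indi_case.append(case_id[r]); indi_seq.append("1"); indi_pt.append(seiz_pt)
    # background mentions occasionally carry a (non-CDP) indication
    ind_pool = np.array(vocab.indication_pts, dtype=object)
    bg_ind = rng_indi.random(total_bg) < config.background_indication_rate
    bg_ind_pt = ind_pool[rng_indi.integers(0, len(ind_pool), size=total_bg)]
    for r in range(n):
        base_seq = 2 if r in cdp_pos else 1
        for k, j in enumerate(range(bg_offsets[r], bg_offsets[r + 1])):
            if bg_ind[j]:
                indi_case.append(case_id[r])
                indi_seq.append(str(base_seq + k))
                indi_pt.append(bg_ind_pt[j])
    indications = pd.DataFrame(
        {"case_id": indi_case, "drug_seq": indi_seq, "pt": indi_pt}
    ).drop_duplicates().reset_index(drop=True)

    # --- reactions (the planted-disproportionality event model) -----------
    pi = vocab.background_probs
    U = _rng(config.seed, "reactions").random((n, n_pts))
    hits = U < pi[None, :]
    for ps in config.planted_signals:
        col = pt_index[ps.pt]
        rows = group_of == ps.group
        if ps.indication_linked:
            rows = rows & cdp_has_ind
        p_eff = min(1.0, pi[col] * ps.rho)
        hits[rows, col] = U[rows, col] < p_eff
    # every report needs >=1 reaction: redraw whole zero rows (rejection),
    # which conditions on >=1 event without distorting relative PT rates
    rng_fill = _rng(config.seed, "reaction-fill")
    zero_rows = np.flatnonzero(~hits.any(axis=1))
    guard = 0
    while len(zero_rows):
        p_sub = np.tile(pi, (len(zero_rows), 1))
        for ps in config.planted_signals:
            mask = group_of[zero_rows] == ps.group
            if ps.indication_linked:
                mask = mask & cdp_has_ind[zero_rows]
            p_sub[mask, pt_index[ps.pt]] = min(1.0, pi[pt_index[ps.pt]] * ps.rho)
        new = rng_fill.random(p_sub.shape) < p_sub
        guard += 1
        if guard > 200:  # degenerate probabilities: fall back to the modal PT
            new[:, int(np.argmax(pi))] = True
        hits[zero_rows] = new
        zero_rows = zero_rows[~new.any(axis=1)]
    rr, cc = np.nonzero(hits)
    reactions = pd.DataFrame({"case_id": case_id[rr], "pt": pt_ids[cc]})

    # --- outcomes ----------------------------------------------------------
    rng_outc = _rng(config.seed, "outcomes")
    outc_case, outc_code = [], []
    outcome_sets: list[set] = [set() for _ in range(n)]
    for code, p in OUTCOME_PROBS.items():
        hit = rng_outc.random(n) < p
        for r in np.flatnonzero(hit):
            outcome_sets[r].add(code)
            outc_case.append(case_id[r]); outc_code.append(code)
    outcomes = pd.DataFrame({"case_id": outc_case, "code": outc_code})

    # --- duplication plan --------------------------------------------------
    rng_dup = _rng(config.seed, "duplicates")
    n_dup = int(round(config.duplicate_rate * n))
    dup_rows = rng_dup.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    n_versions = np.ones(n, dtype=int)
    if n_dup:
        n_versions[dup_rows] = rng_dup.integers(2, 4, size=n_dup)
    fill_age = np.zeros(n, dtype=bool)
    add_outcome = np.zeros(n, dtype=bool)
    if n_dup:
        fill_age[dup_rows] = age_missing[dup_rows] & (rng_dup.random(n_dup) < 0.5)
        add_outcome[dup_rows] = rng_dup.random(n_dup) < 0.5
    fill_age_val = np.round(np.abs(rng_dup.normal(45.0, 20.0, size=n)), 1)
    extra_code = np.empty(n, dtype=object)
    extra_code[:] = None
    for r in np.flatnonzero(add_outcome):
        for cand in ("OT", "HO", "DE"):
            if cand not in outcome_sets[r]:
                extra_code[r] = cand
                break

    # --- final (deduplicated) state ---------------------------------------
    final_age = np.full(n, np.nan)
    present = ~age_missing
    final_age[present] = np.array(
        [float(s) for s in age_stored[present]]
    ) * factors[present]
    filled_rows = np.flatnonzero(fill_age)
    final_age[filled_rows] = np.array([float(f"{v:.1f}") for v in fill_age_val[filled_rows]])
    sex_final = np.where(sex_missing, "missing", np.where(sex_female, "female", "male"))
    version_id = (case_num * 10 + n_versions).astype(str)

    demo = pd.DataFrame(
        {
            "case_id": case_id,
            "version_id": version_id,
            "init_quarter": np.array(config.quarters, dtype=object)[init_q_idx],
            "age_years": final_age,
            "sex": sex_final,
            "country": [c if c is not None else pd.NA for c in country],
        }
    )
    extra_rows = np.flatnonzero(pd.notna(pd.Series(extra_code)))
    if len(extra_rows):
        outcomes = pd.concat(
            [outcomes, pd.DataFrame({"case_id": case_id[extra_rows],
                                     "code": extra_code[extra_rows]})],
            ignore_index=True,
        )

    rs = ReportSet(
        demo, drugs, reactions.drop_duplicates(), outcomes.drop_duplicates(),
        indications,
        period=(config.quarters[0], config.quarters[-1]),
        provenance={"generator_seed": config.seed, "n_reports": n},
    )

    # --- version-level raw tables for the bundle writer --------------------
    rs._versions = _build_version_tables(  # type: ignore[attr-defined]
        config, case_num, init_q_idx, n_versions, age_stored, age_unit,
        fill_age, fill_age_val, sex_female, sex_missing, country,
        drugs, reactions, outcomes, indications, extra_code,
    )

    # --- truth -------------------------------------------------------------
    planted = pd.DataFrame(
        [(ps.group, ps.pt, ps.rho, ps.indication_linked) for ps in config.planted_signals],
        columns=["group", "pt", "rho", "indication_linked"],
    )
    case_groups = pd.DataFrame(
        {"case_id": case_id[cdp_rows], "group": group_of[cdp_rows]}
    ).reset_index(drop=True)
    term_groups = (
        pd.DataFrame(
            {"verbatim_term": [normalize_term(t) for t in cdp_term],
             "group": group_of[cdp_rows]}
        )
        .drop_duplicates("verbatim_term")
        .reset_index(drop=True)
    )
    q_arr = np.array(config.quarters, dtype=object)[init_q_idx]
    per_quarter = pd.Series(q_arr).value_counts().sort_index()
    per_group = pd.Series(group_of[cdp_rows]).value_counts()
    manifest = {
        "config": _config_to_dict(config),
        "n_cases": int(n),
        "n_duplicated_cases": int(n_dup),
        "n_versions_total": int(n_versions.sum()),
        "per_quarter_init_counts": {k: int(v) for k, v in per_quarter.items()},
        "per_group_counts": {k: int(v) for k, v in per_group.items()},
        "cdp_role_probs": {g: list(GROUP_PROFILES[g]["roles"]) for g in group_names},
        "n_missing_age_initial": int(age_missing.sum()),
        "n_missing_age_final": int(age_missing.sum() - fill_age.sum()),
        "n_missing_sex": int(sex_missing.sum()),
        "n_cdp_terms_emitted": int(len(term_groups)),
        "n_cdp_with_seizure_indication": int(cdp_has_ind.sum()),
        "background_probs": [float(x) for x in pi],
        "outcome_probs": dict(OUTCOME_PROBS),
    }
    truth = SimulationTruth(planted, case_groups, term_groups, manifest)
    return rs, truth


def _config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["quarters"] = list(config.quarters)
    d["cdp_group_weights"] = dict(config.cdp_group_weights)
    d["indication_rates"] = dict(config.indication_rates)
    d["planted_signals"] = [asdict(ps) for ps in config.planted_signals]
    return d


def _build_version_tables(
    config, case_num, init_q_idx, n_versions, age_stored, age_unit,
    fill_age, fill_age_val, sex_female, sex_missing, country,
    drugs, reactions, outcomes, indications, extra_code,
):
    """Per-version raw tables in the on-disk column layout."""
    n = len(case_num)
    nq = len(config.quarters)
    case_id = case_num.astype(str)
    sex_code = np.where(sex_missing, "", np.where(sex_female, "F", "M"))
    country_code = np.array([c if c is not None else "" for c in country], dtype=object)

    demo_rows = []
    for k in (1, 2, 3):
        rows = np.flatnonzero(n_versions >= k)
        if not len(rows):
            continue
        q_idx = np.minimum(init_q_idx[rows] + (k - 1), nq - 1)
        is_last = n_versions[rows] == k
        ages = age_stored[rows].copy()
        units = age_unit[rows].copy()
        filled = is_last & fill_age[rows]
        ages[filled] = np.array(
            [f"{v:.1f}" for v in fill_age_val[rows][filled]], dtype=object
        )
        units[filled] = "YR"
        demo_rows.append(
            pd.DataFrame(
                {
                    "primaryid": (case_num[rows] * 10 + k).astype(str),
                    "caseid": case_id[rows],
                    "caseversion": str(k),
                    "fda_dt": [
                        quarter_start_date(config.quarters[i]) for i in q_idx
                    ],
                    "age": ages,
                    "age_cod": units,
                    "sex": sex_code[rows],
                    "occr_country": country_code[rows],
                    "quarter": [config.quarters[i] for i in q_idx],
                }
            )
        )
    demo_v = pd.concat(demo_rows, ignore_index=True)

    # quarter of each (caseid, caseversion) for the satellite tables
    vmap = demo_v[["primaryid", "caseid", "caseversion", "quarter"]]

    def _explode(case_level: pd.DataFrame, cols_map: dict[str, str],
                 final_only_extra: pd.DataFrame | None = None) -> pd.DataFrame:
        base = case_level.rename(columns={"case_id": "caseid"})
        merged = vmap.merge(base, on="caseid", how="inner")
        return merged

    drug_v = _explode(drugs, {})
    drug_v = drug_v.rename(columns={"role": "role_cod", "verbatim_name": "drugname"})
    reac_v = _explode(reactions, {})
    indi_v = _explode(indications, {})
    indi_v = indi_v.rename(columns={"drug_seq": "indi_drug_seq", "pt": "indi_pt"})

    # outcomes: the extra code exists only in the final version
    extra_mask = np.array([c is not None for c in extra_code])
    extra_df = pd.DataFrame(
        {"caseid": case_id[extra_mask], "code": extra_code[extra_mask]}
    )
    base_outc = outcomes.rename(columns={"case_id": "caseid"})
    if len(extra_df):
        key = set(zip(extra_df["caseid"], extra_df["code"]))
        base_outc = base_outc[
            [
                (c, o) not in key
                for c, o in zip(base_outc["caseid"], base_outc["code"])
            ]
        ]
    outc_all = vmap.merge(base_outc, on="caseid", how="inner")
    if len(extra_df):
        last = vmap.copy()
        last["caseversion_n"] = last["caseversion"].astype(int)
        last = last.sort_values(["caseid", "caseversion_n"]).groupby("caseid").tail(1)
        outc_extra = last.merge(extra_df, on="caseid", how="inner")
        outc_all = pd.concat(
            [outc_all, outc_extra[outc_all.columns]], ignore_index=True
        )
    outc_v = outc_all.rename(columns={"code": "outc_cod"})

    return {
        "DEMO": demo_v,
        "DRUG": drug_v[["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "quarter"]],
        "REAC": reac_v[["primaryid", "caseid", "pt", "quarter"]],
        "OUTC": outc_v[["primaryid", "caseid", "outc_cod", "quarter"]],
        "INDI": indi_v[["primaryid", "caseid", "indi_drug_seq", "indi_pt", "quarter"]],
    }


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------


def write_quarterly_bundle(reports: ReportSet, out_dir: str | Path) -> list[Path]:
    """Write '$'-delimited quarterly DEMO/DRUG/REAC/OUTC/INDI files.

    For generator output the attached version-level tables are written, so
    duplicated cases appear as multiple versions in their respective
    quarters; a plain report set is written as one version per case.
    Returns the list of written paths (one file per table per quarter).
    """
    if len(reports) == 0:
        raise ValueError("cannot write an empty report set")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    versions = getattr(reports, "_versions", None)
    if versions is None:
        versions = _single_version_tables(reports)
    quarters = sorted(
        set().union(*(set(v["quarter"]) for v in versions.values())),
    )
    paths = []
    for table in TABLES:
        df = versions[table]
        cols = list(COLUMNS[table])
        for q in quarters:
            sub = df[df["quarter"] == q]
            path = out / f"{table}{q}.txt"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("$".join(cols) + "\n")
                if len(sub):
                    block = sub[cols].astype(str).replace({"nan": "", "<NA>": ""})
                    for row in block.itertuples(index=False):
                        fh.write("$".join(row) + "\n")
            paths.append(path)
    return paths


def _single_version_tables(rs: ReportSet) -> dict[str, pd.DataFrame]:
    demo = rs.demo
    age = demo["age_years"]
    demo_v = pd.DataFrame(
        {
            "primaryid": demo["case_id"].astype(str) + "1",
            "caseid": demo["case_id"].astype(str),
            "caseversion": "1",
            "fda_dt": demo["init_quarter"].map(quarter_start_date),
            "age": [("" if pd.isna(v) else f"{v:.4f}") for v in age],
            "age_cod": ["" if pd.isna(v) else "YR" for v in age],
            "sex": demo["sex"].map({"female": "F", "male": "M"}).fillna(""),
            "occr_country": demo["country"].fillna(""),
            "quarter": demo["init_quarter"],
        }
    )
    vmap = demo_v[["primaryid", "caseid", "quarter"]]

    def _j(df, renames):
        out = df.rename(columns={"case_id": "caseid", **renames})
        return vmap.merge(out, on="caseid", how="inner")

    return {
        "DEMO": demo_v,
        "DRUG": _j(rs.drugs, {"role": "role_cod", "verbatim_name": "drugname"})[
            ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "quarter"]
        ],
        "REAC": _j(rs.reactions, {})[["primaryid", "caseid", "pt", "quarter"]],
        "OUTC": _j(rs.outcomes, {"code": "outc_cod"})[
            ["primaryid", "caseid", "outc_cod", "quarter"]
        ],
        "INDI": _j(rs.indications, {"drug_seq": "indi_drug_seq", "pt": "indi_pt"})[
            ["primaryid", "caseid", "indi_drug_seq", "indi_pt", "quarter"]
        ],
    }


# ---------------------------------------------------------------------------
# preset study conditions
# ---------------------------------------------------------------------------


def null_config(n_reports: int = 200_000, seed: int = 0) -> GeneratorConfig:
    """All reporting-rate ratios at 1: the calibration condition."""
    return GeneratorConfig(n_reports=n_reports, seed=seed)


def signal_config(
    n_reports: int = 120_000, seed: int = 0
) -> tuple[GeneratorConfig, Vocabulary]:
    """Planted-signal condition for recovery/power checks.

    PTs are chosen from the vocabulary so that each planted pair has an
    expected exposed-with-event count of at least ~10 at the configured
    group sizes, with one clearly strongest pair (largest rho) for the
    ranking check.
    """
    base = GeneratorConfig(n_reports=n_reports, seed=seed)
    vocab = make_vocabulary(base)
    pi = vocab.background_probs
    planted = []
    specs = [("CBD", 8.0, 24.0), ("Cannabis", 4.0, 12.0),
             ("Epidiolex", 4.0, 12.0), ("CBD", 4.0, 12.0)]
    used: set[str] = set()
    for g, rho, min_expected in specs:
        n_g = n_reports * base.cdp_group_weights[g]
        ok = [
            i
            for i in np.argsort(pi)
            if pi[i] * rho <= 0.5
            and n_g * min(1.0, pi[i] * rho) >= min_expected
            and vocab.pt_ids[i] not in used
        ]
        if not ok:
            raise ValueError(f"no suitable PT for planting in group {g}")
        pt = vocab.pt_ids[ok[0]]
        used.add(pt)
        planted.append(PlantedSignal(group=g, pt=pt, rho=rho))
    return replace(base, planted_signals=tuple(planted)), vocab


def subgroup_config(
    n_reports: int = 120_000, seed: int = 0
) -> tuple[GeneratorConfig, Vocabulary]:
    """Two-group indication-linked condition (pharma vs non-pharma CBD).

    Seizure-type events are planted for the pharmaceutical group only and
    only within reports carrying the seizure-like indication; the
    non-pharmaceutical group gets non-seizure planted events unrelated to
    the indication.
    """
    base = GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        cdp_group_weights={"Epidiolex": 0.08, "CBD": 0.06},
        indication_rates={"Epidiolex": 0.80, "CBD": 0.08},
    )
    vocab = make_vocabulary(base)
    seiz = vocab.seizure_pts()[:3]
    planted = [
        PlantedSignal(group="Epidiolex", pt=pt, rho=8.0, indication_linked=True)
        for pt in seiz
    ]
    pi = vocab.background_probs
    seiz_set = set(seiz)
    non_seiz = [
        i for i in np.argsort(pi)[::-1]
        if vocab.pt_ids[i] not in seiz_set and pi[i] * 6.0 <= 0.5
    ][:3]
    planted += [
        PlantedSignal(group="CBD", pt=vocab.pt_ids[i], rho=6.0) for i in non_seiz
    ]
    return replace(base, planted_signals=tuple(planted)), vocab
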