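"""Rule-based pathway-completeness auditing of enzyme inventories.

A pathway is encoded as ordered steps, each a disjunction of alternative
enzymes; the pathway is a conjunction across steps.  Entry substrates
mark points where a host-supplied metabolite can enter, so a strain
missing only upstream steps is *conditionally* capable given that
substrate.  Pseudogenes (e.g. a frameshifted gene) count as absent in
capability logic.

The packaged definitions cover the five phytohormone-relevant pathways
audited for *Wolbachia*-style endosymbionts: the MEP route to the prenyl
donors DMAPP/HMBDP (KEGG map 00900), SAM synthesis from aspartate or
homoserine (map 00270), tRNA-bound cytokinin production (map 00908),
tryptophan-dependent IAA synthesis (map 00380), and adenine salvage
(map 00230).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd

Status = Literal["present", "absent", "pseudogene"]

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
_STATUSES = ("present", "absent", "pseudogene")

#: verdict ordering used by the monotonicity contract
VERDICT_ORDER = {"incapable": 0, "conditional": 1, "capable": 2}


def normalize_key(key: str) -> str:
    """EC numbers kept as-is, gene symbols lowercased."""
    key = key.strip()
    return key if _EC_RE.match(key) else key.lower()


@dataclass
class Enzyme:
    key: str  # canonical catalog key (lowercase symbol)
    name: str
    symbol: str
    ecs: list[str] = field(default_factory=list)

    def lookup_keys(self) -> list[str]:
        # EC match first, gene symbol as fallback
        return [*self.ecs, self.symbol]


@dataclass
class EnzymeProfile:
    """One strain's enzyme inventory: normalized key -> status."""

    strain_id: str
    entries: dict[str, Status]

    def __post_init__(self) -> None:
        norm = {}
        for k, v in self.entries.items():
            if v not in _STATUSES:
                raise ValueError(f"unknown status {v!r} for {k} in {self.strain_id}")
            norm[normalize_key(k)] = v
        self.entries = norm

    def status_of(self, enzyme: Enzyme) -> Status:
        for k in enzyme.lookup_keys():
            if k in self.entries:
                return self.entries[k]
        return "absent"


@dataclass
class PathwayStep:
    name: str
    alternatives: list[Enzyme]


@dataclass
class EntrySubstrate:
    substrate: str
    enters_at_step: int


@dataclass
class PathwayDef:
    pathway_id: str
    name: str
    products: list[str]
    entry_substrates: list[EntrySubstrate]
    steps: list[PathwayStep]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"{self.pathway_id}: pathway needs at least one step")
        for step in self.steps:
            if not step.alternatives:
                raise ValueError(f"{self.pathway_id}: step {step.name!r} is empty")
        for es in self.entry_substrates:
            if not (0 <= es.enters_at_step < len(self.steps)):
                raise ValueError(
                    f"{self.pathway_id}: entry substrate {es.substrate!r} maps to "
                    f"invalid step {es.enters_at_step}"
                )

    def enzymes(self) -> list[Enzyme]:
        seen: dict[str, Enzyme] = {}
        for step in self.steps:
            for enz in step.alternatives:
                seen.setdefault(enz.key, enz)
        return list(seen.values())


@dataclass
class CapabilityVerdict:
    strain_id: str
    pathway_id: str
    verdict: str  # capable | conditional | incapable
    required_supplements: list[str] = field(default_factory=list)
    missing_steps: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict == "conditional" and not self.required_supplements:
            raise ValueError("conditional verdict requires supplements")
        if self.verdict == "capable" and self.missing_steps:
            raise ValueError("capable verdict cannot carry missing steps")


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def _parse_defs(doc: dict) -> list[PathwayDef]:
    catalog_raw = doc.get("enzymes", {})
    catalog: dict[str, Enzyme] = {}
    for key, spec in catalog_raw.items():
        key = normalize_key(key)
        catalog[key] = Enzyme(
            key=key,
            name=spec.get("name", key),
            symbol=normalize_key(spec.get("symbol", key)),
            ecs=list(spec.get("ec", [])),
        )
    defs = []
    for p in doc.get("pathways", []):
        steps = []
        for s in p.get("steps", []):
            alts = []
            for key in s.get("alternatives", []):
                key = normalize_key(key)
                if key not in catalog:
                    raise ValueError(
                        f"pathway {p.get('id')}: unknown enzyme key {key!r} in step "
                        f"{s.get('name')!r}"
                    )
                alts.append(catalog[key])
            steps.append(PathwayStep(name=s.get("name", ""), alternatives=alts))
        defs.append(
            PathwayDef(
                pathway_id=p["id"],
                name=p.get("name", p["id"]),
                products=list(p.get("products", [])),
                entry_substrates=[
                    EntrySubstrate(e["substrate"], int(e["enters_at_step"]))
                    for e in p.get("entry_substrates", [])
                ],
                steps=steps,
            )
        )
    return defs


def load_pathway_defs(path: str | Path | None = None) -> list[PathwayDef]:
    """Load pathway definitions; the packaged set covers the five audited
    phytohormone-precursor pathways."""
    if path is None:
        text = resources.files("symsift").joinpath("data/pathways.json").read_text()
    else:
        text = Path(path).read_text()
    return _parse_defs(json.loads(text))


def save_pathway_defs(defs: list[PathwayDef], path: str | Path) -> None:
    catalog: dict[str, dict] = {}
    pathways = []
    for d in defs:
        for enz in d.enzymes():
            catalog[enz.key] = {"name": enz.name, "symbol": enz.symbol, "ec": enz.ecs}
        pathways.append(
            {
                "id": d.pathway_id,
                "name": d.name,
                "products": d.products,
                "entry_substrates": [
                    {"substrate": e.substrate, "enters_at_step": e.enters_at_step}
                    for e in d.entry_substrates
                ],
                "steps": [
                    {"name": s.name, "alternatives": [a.key for a in s.alternatives]}
                    for s in d.steps
                ],
            }
        )
    doc = {"schema": "symsift-pathways-v1", "enzymes": catalog, "pathways": pathways}
    Path(path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_pathway(profile: EnzymeProfile, pathway: PathwayDef) -> CapabilityVerdict:
    """Adjudicate one strain against one pathway.

    A step is satisfied iff at least one alternative enzyme is *present*
    (pseudogene == absent).  capable: every step satisfied from the
    natural start.  conditional: all unsatisfied steps precede some entry
    substrate's entry point (the earliest such substrate(s) are the
    minimal required supplements).  Otherwise incapable.
    """
    satisfied = []
    missing_steps = []
    for i, step in enumerate(pathway.steps):
        statuses = [profile.status_of(enz) for enz in step.alternatives]
        ok = any(s == "present" for s in statuses)
        satisfied.append(ok)
        if not ok:
            missing_steps.append(
                {
                    "step": step.name,
                    "index": i,
                    "enzymes": [
                        {
                            "key": enz.key,
                            "cause": "pseudogene" if st == "pseudogene" else "absent",
                        }
                        for enz, st in zip(step.alternatives, statuses)
                    ],
                }
            )
    unsat = [i for i, ok in enumerate(satisfied) if not ok]
    if not unsat:
        return CapabilityVerdict(profile.strain_id, pathway.pathway_id, "capable")
    eligible = [
        es
        for es in pathway.entry_substrates
        if es.enters_at_step > 0 and all(u < es.enters_at_step for u in unsat)
    ]
    if eligible:
        first = min(es.enters_at_step for es in eligible)
        supplements = [es.substrate for es in eligible if es.enters_at_step == first]
        return CapabilityVerdict(
            profile.strain_id,
            pathway.pathway_id,
            "conditional",
            required_supplements=supplements,
            missing_steps=missing_steps,
        )
    return CapabilityVerdict(
        profile.strain_id, pathway.pathway_id, "incapable", missing_steps=missing_steps
    )


def warn_unknown_profile_keys(
    profile: EnzymeProfile, defs: list[PathwayDef]
) -> set[str]:
    """Profile keys that match no definition (ignored with a warning)."""
    known: set[str] = set()
    for d in defs:
        for enz in d.enzymes():
            known.update(enz.lookup_keys())
    unknown = {k for k in profile.entries if k not in known}
    if unknown:
        warnings.warn(
            f"{profile.strain_id}: enzyme keys not used by any pathway definition "
            f"ignored: {sorted(unknown)}",
            stacklevel=2,
        )
    return unknown


# ---------------------------------------------------------------------------
# cross-strain summaries
# ---------------------------------------------------------------------------

@dataclass
class StrainSummary:
    pathway_id: str
    n_strains: int
    missing_fraction: dict[str, float]  # enzyme key -> fraction of strains != present
    missing_count_distribution: dict[int, int]  # missing enzymes per strain -> n strains
    verdict_fractions: dict[str, float]


def summarize_strains(
    profiles: list[EnzymeProfile], pathway: PathwayDef
) -> StrainSummary:
    """Cross-strain enzymatic-loss summary for one pathway."""
    if not profiles:
        raise ValueError("need at least one profile")
    enzymes = pathway.enzymes()
    n = len(profiles)
    missing_fraction = {
        enz.key: sum(1 for p in profiles if p.status_of(enz) != "present") / n
        for enz in enzymes
    }
    dist: dict[int, int] = {}
    verdict_counts = {"capable": 0, "conditional": 0, "incapable": 0}
    for p in profiles:
        n_missing = sum(1 for enz in enzymes if p.status_of(enz) != "present")
        dist[n_missing] = dist.get(n_missing, 0) + 1
        verdict_counts[evaluate_pathway(p, pathway).verdict] += 1
    return StrainSummary(
        pathway_id=pathway.pathway_id,
        n_strains=n,
        missing_fraction=missing_fraction,
        missing_count_distribution=dict(sorted(dist.items())),
        verdict_fractions={k: v / n for k, v in verdict_counts.items()},
    )


def profiles_from_tsv(path: str | Path) -> list[EnzymeProfile]:
    """Read strain profiles from a TSV with columns strain, enzyme_key, status."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for strain, sub in df.groupby("strain", sort=False):
        entries = dict(zip(sub["enzyme_key"], sub["status"]))
        profiles.append(EnzymeProfile(strain_id=str(strain), entries=entries))
    return profiles
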