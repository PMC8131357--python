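"""Semi-automated pollinator roster construction.

The pipeline mirrors the literature-evidence workflow used to decide which
taxa in a survey table count as pollinators:

1. scan abstracts for Latin binomials whose genus is on a reference animal
   taxonomy (:func:`extract_binomials`);
2. classify the evidence sentence for each genus into a confidence level
   1–4 — 1 experimental pollination, 2 pollen carrying, 3 nectar/pollen
   feeding, 4 non-destructive/non-predatory flower visitation — or flag
   contrary evidence (destructive or predatory visitors, the ant /
   crab-spider case) (:func:`evidence_from_corpus`);
3. keep each genus at its best (numerically lowest) level
   (:func:`assign_confidence`), genera with only contrary evidence going to
   a blocklist;
4. extrapolate genus evidence to whole families/subfamilies/tribes where it
   spans multiple branches and nothing in the group argues against
   (:func:`extrapolate_groups`);
5. merge with precedence, apply expert edit lists, and filter a survey
   table down to pollinator records (:func:`compile_roster`,
   :func:`filter_records`).

Confidence semantics: smaller numbers are stronger evidence.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TaxonEvidence", "RosterEntry", "Roster", "extract_binomials",
    "evidence_from_corpus", "assign_confidence", "extrapolate_groups",
    "compile_roster", "filter_records", "read_edit_list",
]

log = logging.getLogger(__name__)

GROUP_LEVELS = ("family", "subfamily", "tribe")   # descending rank order


class DataError(ValueError):
    """Malformed taxonomy or survey input."""


@dataclass(frozen=True)
class TaxonEvidence:
    genus: str
    evidence_level: int | None      # 1..4, or None for a negative record
    negative: bool = False
    source_id: str = ""

    def __post_init__(self):
        if self.negative:
            if self.evidence_level is not None:
                raise ValueError("a record cannot be both positive and negative")
        elif self.evidence_level not in (1, 2, 3, 4):
            raise ValueError("evidence_level must be in 1..4")


@dataclass(frozen=True)
class RosterEntry:
    taxon: str
    level: str                      # genus | tribe | subfamily | family
    confidence: object              # int 1..4, or "extrapolated"/"expert"
    provenance: str                 # direct | extrapolated | expert_added


@dataclass
class Roster:
    entries: list = field(default_factory=list)
    blocklist: set = field(default_factory=set)
    covered_genera: set = field(default_factory=set)   # expansion via taxonomy

    def genus_confidence(self) -> dict:
        """genus -> confidence for direct/expert genus-level entries."""
        return {e.taxon: e.confidence for e in self.entries
                if e.level == "genus"}

    def group_set(self) -> set:
        return {(e.taxon, e.level) for e in self.entries if e.level != "genus"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.taxon, e.level, e.confidence, e.provenance)
             for e in self.entries],
            columns=["taxon", "level", "confidence", "provenance"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# scanner: capitalised genus token followed by a lowercase epithet of >= 3
# letters; the genus must match the reference list exactly (no fuzzy match)
_BINOMIAL_RE = re.compile(r"\b([A-Z][a-z]+) ([a-z]{3,})\b")

# cue lexicon keyed on the phrasing classes of the evidence sentences
_CUE_PATTERNS = [
    (1, re.compile(r"exclusion experiment|fruit set depend|experimental(ly)? "
                   r"confirm\w* pollinat", re.I)),
    (2, re.compile(r"carr\w+ (substantial )?pollen|pollen load", re.I)),
    (3, re.compile(r"feed\w* on nectar|nectar and pollen|nectar[- ]feeding", re.I)),
    (4, re.compile(r"visit\w+ flowers without|non-?destructive\w* visit", re.I)),
]
_NEGATIVE_PATTERN = re.compile(
    r"destructiv|robbed flowers|preyed upon|predat\w+ (on|upon)", re.I)


def extract_binomials(text: str, taxonomy: pd.DataFrame) -> set:
    """Genera appearing as Latin binomials in ``text`` and on the reference list."""
    if taxonomy.empty:
        raise DataError("reference taxonomy is empty")
    known = set(taxonomy["genus"])
    return {m.group(1) for m in _BINOMIAL_RE.finditer(text)
            if m.group(1) in known}


def evidence_from_corpus(corpus: dict, taxonomy: pd.DataFrame) -> list:
    """Scan every abstract for reference-matched genera and evidence cues.

    Each (abstract, genus) pair yields at most one record: a negative record
    if the abstract carries a contrary-evidence cue, else a positive record
    at the strongest cue level found, else nothing (mention without
    evidence, which the workflow does not count).
    """
    out = []
    for aid, text in corpus.items():
        genera = extract_binomials(text, taxonomy)
        if not genera:
            continue
        if _NEGATIVE_PATTERN.search(text):
            for g in genera:
                out.append(TaxonEvidence(g, None, negative=True, source_id=aid))
            continue
        levels = [lv for lv, pat in _CUE_PATTERNS if pat.search(text)]
        if levels:
            best = min(levels)
            for g in genera:
                out.append(TaxonEvidence(g, best, source_id=aid))
    return out


def assign_confidence(evidence: list) -> tuple[dict, set]:
    """Best (lowest) positive level per genus, plus the blocklist.

    Genera with only negative records are excluded from the confidence map
    and placed on the blocklist; a genus with any positive record keeps its
    best positive level.
    """
    conf: dict[str, int] = {}
    negative: set = set()
    for ev in evidence:
        if ev.negative:
            negative.add(ev.genus)
        else:
            cur = conf.get(ev.genus)
            conf[ev.genus] = ev.evidence_level if cur is None \
                else min(cur, ev.evidence_level)
    blocklist = negative - set(conf)
    return conf, blocklist


def _check_taxonomy(taxonomy: pd.DataFrame) -> None:
    need = {"genus", "family"}
    if not need <= set(taxonomy.columns):
        raise DataError("taxonomy needs genus and family columns")
    fam_per_genus = taxonomy.groupby("genus")["family"].nunique()
    if (fam_per_genus > 1).any():
        bad = fam_per_genus[fam_per_genus > 1].index.tolist()
        raise DataError(f"genus under two families: {bad}")
    if taxonomy["family"].isna().any():
        raise DataError("orphan genus with no family")


def extrapolate_groups(confident_genera: dict, blocklist: set,
                       taxonomy: pd.DataFrame, min_branches: int = 2) -> list:
    """Promote genus evidence to the highest whole group it supports.

    For each family: if at least ``min_branches`` distinct immediate
    sub-lineages contain a confident genus and no genus of the family is
    blocklisted, the whole family is entered; otherwise the same rule is
    applied one rank down (subfamily, then tribe). A genus with no
    subfamily recorded forms its own immediate lineage of the family, and
    likewise for tribes within subfamilies. Contrary evidence blocks the
    containing group but never removes sibling genera.
    """
    if min_branches < 2:
        raise ValueError("min_branches must be >= 2")
    _check_taxonomy(taxonomy)
    confident = set(confident_genera)
    out: list[RosterEntry] = []

    def branch_key(row, child_col):
        v = row.get(child_col)
        return v if pd.notna(v) else "genus:" + row["genus"]

    def qualify(df, level, taxon, child_col):
        if set(df["genus"]) & blocklist:
            return False
        branches = {branch_key(r, child_col)
                    for _, r in df.iterrows() if r["genus"] in confident}
        return len(branches) >= min_branches

    for family, fam in taxonomy.groupby("family"):
        if qualify(fam, "family", family, "subfamily"):
            out.append(RosterEntry(family, "family", "extrapolated",
                                   "extrapolated"))
            continue
        if "subfamily" not in fam.columns:
            continue
        for sub, subdf in fam.dropna(subset=["subfamily"]).groupby("subfamily"):
            if qualify(subdf, "subfamily", sub, "tribe"):
                out.append(RosterEntry(sub, "subfamily", "extrapolated",
                                       "extrapolated"))
                continue
            if "tribe" not in subdf.columns:
                continue
            for tribe, trdf in subdf.dropna(subset=["tribe"]).groupby("tribe"):
                # at the tribe level the immediate lineages are the genera
                if set(trdf["genus"]) & blocklist:
                    continue
                if len(set(trdf["genus"]) & confident) >= min_branches:
                    out.append(RosterEntry(tribe, "tribe", "extrapolated",
                                           "extrapolated"))
    return out


def _genera_under(taxonomy: pd.DataFrame, taxon: str, level: str) -> set:
    if level == "genus":
        return {taxon}
    if level not in taxonomy.columns:
        return set()
    return set(taxonomy.loc[taxonomy[level] == taxon, "genus"])


def compile_roster(direct: dict, groups: list, taxonomy: pd.DataFrame,
                   edits: list | None = None, blocklist: set | None = None
                   ) -> Roster:
    """Merge direct evidence, group extrapolations, and expert edits.

    Direct genus entries are inserted first so every genus is picked up at
    its best level of confidence and carries exactly one value. Expert
    removals strip entries and the genera they imply, but a removal of a
    group does not delete genera inside it that have their own direct
    evidence — "highly unlikely pollinator" removals by definition target
    taxa without credible direct evidence. ``edits`` is a list of
    (action, taxon, level) with action in {"add", "remove"}.

    Compiling is idempotent: feeding a compiled roster's entries back in
    changes nothing.
    """
    edits = edits or []
    blocklist = set(blocklist or ())
    entries: list[RosterEntry] = []
    seen: set = set()

    for genus in sorted(direct):
        e = RosterEntry(genus, "genus", direct[genus], "direct")
        entries.append(e)
        seen.add((e.taxon, e.level))
    for e in sorted(groups, key=lambda e: (GROUP_LEVELS.index(e.level), e.taxon)):
        if (e.taxon, e.level) in seen:
            continue
        entries.append(e)
        seen.add((e.taxon, e.level))

    for action, taxon, level in edits:
        if action == "remove":
            if (taxon, level) not in seen:
                warnings.warn(f"removal of absent taxon {taxon} ({level})")
                continue
            entries = [e for e in entries
                       if not (e.taxon == taxon and e.level == level)]
            seen.discard((taxon, level))
        elif action == "add":
            if (taxon, level) in seen:
                continue
            entries.append(RosterEntry(taxon, level, "expert", "expert_added"))
            seen.add((taxon, level))
        else:
            raise ValueError(f"unknown edit action {action!r}")

    roster = Roster(entries=entries, blocklist=blocklist)
    covered: set = set()
    for e in entries:
        covered |= _genera_under(taxonomy, e.taxon, e.level)
    roster.covered_genera = covered
    return roster


def read_edit_list(path) -> list:
    """Expert edit list from CSV (columns: action, taxon, level) or YAML."""
    path = str(path)
    if path.endswith((".yml", ".yaml")):
        import yaml
        with open(path) as fh:
            items = yaml.safe_load(fh) or []
        return [(d["action"], d["taxon"], d["level"]) for d in items]
    df = pd.read_csv(path)
    return list(df[["action", "taxon", "level"]].itertuples(index=False,
                                                            name=None))


def filter_records(survey: pd.DataFrame, roster: Roster) -> pd.DataFrame:
    """Keep pollinator records; drop sites (and studies) left empty.

    A record survives when its genus carries direct/expert evidence or
    belongs to an extrapolated group (the roster's genus expansion, built
    against the reference taxonomy at compile time).
    """
    for col in ("Genus", "Family"):
        if col not in survey.columns:
            raise DataError(f"survey table lacks required column {col}")
    keep_genera = roster.covered_genera | set(roster.genus_confidence())
    out = survey[survey["Genus"].isin(keep_genera)].copy()
    n_sites_in = survey["SSBS"].nunique() if "SSBS" in survey else None
    if n_sites_in is not None:
        log.info("filter_records: %d -> %d records, %d -> %d sites",
                 len(survey), len(out), n_sites_in, out["SSBS"].nunique())
    return out.reset_index(drop=True)
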