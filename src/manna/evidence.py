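"""Evidence summarization for the annotation decision guide.

Raw hits from each (tool, database) search are reduced to the qualitative
predicates a curator weighs when choosing a label: did the database return
results, how significant are they, do the top hits agree with each other
(within a database and across databases), is the subject a similar length to
the query, and how much of query and subject does the alignment cover.  The
numeric boundaries behind each predicate live in
:class:`manna.config.Thresholds`.

This module also produces the genome-map data product (the static counterpart
of the interactive genome view, emitted only for genomes with fewer than 1000
features) and the e-value colour scale used when rendering hits: black at
e-value 10 grading to light yellow at e-value 0, linear in log10 space.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import Thresholds, DEFAULT_THRESHOLDS
from .errors import NotFoundError, ValidationError
from .homology import Hit, is_supported_combo
from .store import Store

LABEL_STOPWORDS = frozenset(
    {
        "protein",
        "putative",
        "probable",
        "predicted",
        "hypothetical",
        "family",
        "domain",
        "phage",
        "uncharacterized",
        "conserved",
    }
)

# databases ranked by curation quality, most curated first
CURATION_ORDER = (
    ("blastp", "internal"),
    ("blastp", "swissprot"),
    ("rpsblast", "cdd"),
    ("hhsearch", "pdb"),
    ("blastp", "nr"),
)


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------

def coverage_fractions(hit: Hit, query_length: int) -> tuple[float, float]:
    """(query coverage, subject coverage) of one alignment, each in (0, 1]."""
    q_cov = (hit.q_end - hit.q_start + 1) / query_length
    s_cov = (hit.s_end - hit.s_start + 1) / hit.subject_length
    return q_cov, s_cov


def classify_significance(
    hit: Hit, tool: str, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """'significant', 'moderate' or 'none' for one hit.

    blastp / rpsblast classify on e-value; hhsearch on the probability
    carried in ``hit.score``.
    """
    if tool == "hhsearch":
        if hit.score >= thresholds.hh_prob_significant:
            return "significant"
        if hit.score >= thresholds.hh_prob_moderate:
            return "moderate"
        return "none"
    if hit.evalue <= thresholds.evalue_significant:
        return "significant"
    if hit.evalue <= thresholds.evalue_moderate:
        return "moderate"
    return "none"


def normalize_label(text: str) -> list[str]:
    """Tokenize a product label for comparison.

    Lowercases, strips punctuation and brackets, splits on whitespace and
    hyphens, and drops generic filler words so that e.g. "Putative terminase,
    large subunit" and "terminase large subunit" compare equal.
    """
    text = re.sub(r"[^\w\s]", " ", text.lower().replace("-", " "))
    return [t for t in text.split() if t and t not in LABEL_STOPWORDS]


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def consistent(
    hits_or_labels: Sequence,
    k: int = 5,
    min_jaccard: float = 0.5,
) -> bool:
    """Do the (top-k) hit labels agree?

    Pairwise Jaccard similarity of normalized token sets must reach
    ``min_jaccard`` for a strict majority of pairs.  Zero or one label is
    vacuously consistent.
    """
    labels = [
        h.subject_description if isinstance(h, Hit) else str(h)
        for h in hits_or_labels[:k]
    ]
    sets = [set(normalize_label(lab)) for lab in labels]
    if len(sets) < 2:
        return True
    good = total = 0
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            total += 1
            if _jaccard(sets[i], sets[j]) >= min_jaccard:
                good += 1
    return 2 * good > total


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class DbEvidence:
    """Qualitative evidence from one (tool, database) search."""

    present: bool = False
    significance: str = "none"  # significant | moderate | none
    consistent_within: bool = False
    top_hit: Optional[Hit] = None
    length_similar: bool = False
    q_coverage_class: str = "negligible"  # all_most | some | negligible
    s_coverage_class: str = "negligible"
    hits: list[Hit] = field(default_factory=list)


@dataclass
class EvidenceSummary:
    """All per-database evidence for one annotation.

    ``version`` counts history events at summary time so that a
    recommendation built from this summary can detect concurrent edits.
    """

    accession: str
    query_length: int
    per_db: dict[tuple[str, str], DbEvidence] = field(default_factory=dict)
    current_label: str = ""
    current_flag: str = "UNANNOTATED"
    version: Optional[int] = None

    def evidence(self, tool: str, database: str) -> DbEvidence:
        return self.per_db.get((tool, database), DbEvidence())


def _coverage_class(fraction: float, thresholds: Thresholds) -> str:
    if fraction >= thresholds.coverage_all_most:
        return "all_most"
    if fraction >= thresholds.coverage_some:
        return "some"
    return "negligible"


def summarize_hits(
    accession: str,
    query_length: int,
    results: dict[tuple[str, str], list[Hit]],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> EvidenceSummary:
    """Build an evidence summary from raw per-(tool, database) hit lists."""
    if query_length <= 0:
        raise ValidationError("query_length must be positive")
    summary = EvidenceSummary(accession=accession, query_length=query_length)
    for (tool, database), hits in results.items():
        if not is_supported_combo(tool, database):
            raise ValidationError(
                f"unsupported search combination: {tool} vs {database}"
            )
        if not hits:
            continue
        if tool == "hhsearch":
            hits = sorted(hits, key=lambda h: (-h.score, h.evalue))
        else:
            hits = sorted(hits, key=lambda h: (h.evalue, -h.score))
        top = hits[0]
        q_cov, s_cov = coverage_fractions(top, query_length)
        lmin, lmax = sorted((query_length, top.subject_length))
        summary.per_db[(tool, database)] = DbEvidence(
            present=True,
            significance=classify_significance(top, tool, thresholds),
            consistent_within=consistent(
                hits, k=thresholds.consistency_top_k,
                min_jaccard=thresholds.consistency_jaccard,
            ),
            top_hit=top,
            length_similar=(lmin / lmax) >= thresholds.length_similar,
            q_coverage_class=_coverage_class(q_cov, thresholds),
            s_coverage_class=_coverage_class(s_cov, thresholds),
            hits=hits,
        )
    return summary


def summarize_evidence(
    store: Store, accession: str, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> EvidenceSummary:
    """Summarize every stored search result for one annotation."""
    ann = store.get_annotation(accession)
    summary = summarize_hits(
        accession, len(ann.sequence), store.search_results_for(accession), thresholds
    )
    summary.current_label = ann.label
    summary.current_flag = ann.flag
    summary.version = len(store.get_history(accession))
    return summary


def consistent_across(
    summary: EvidenceSummary, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Do the top hits of the databases that returned results agree?"""
    tops = [
        ev.top_hit.subject_description
        for ev in summary.per_db.values()
        if ev.present and ev.top_hit is not None
    ]
    tops = [_strip_internal_header(t) for t in tops]
    return consistent(tops, k=len(tops), min_jaccard=thresholds.consistency_jaccard)


def _strip_internal_header(description: str) -> str:
    """Internal-db subjects are encoded 'accession|flag|label'; keep the label."""
    if description.count("|") >= 2 and description.split("|", 1)[0].startswith("MAS_"):
        return description.split("|", 2)[2]
    return description


# ---------------------------------------------------------------------------
# E-value colour scale
# ---------------------------------------------------------------------------

EVALUE_FLOOR = 1e-180
EVALUE_CEILING = 10.0
_LIGHT_YELLOW = (255, 255, 224)  # #FFFFE0


def evalue_color(evalue: float) -> str:
    """Colour for an e-value: black at 10, light yellow at 0.

    Linear interpolation in log10 space, clamped to [1e-180, 10] so the
    logarithm stays finite; smaller e-values map to strictly lighter colours.
    """
    if evalue < 0:
        raise ValidationError("e-value must be non-negative")
    clamped = min(max(evalue, EVALUE_FLOOR), EVALUE_CEILING)
    t = (math.log10(EVALUE_CEILING) - math.log10(clamped)) / (
        math.log10(EVALUE_CEILING) - math.log10(EVALUE_FLOOR)
    )
    rgb = tuple(round(t * c) for c in _LIGHT_YELLOW)
    return "#{:02X}{:02X}{:02X}".format(*rgb)


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------

GENOME_MAP_MAX_FEATURES = 1000

FLAG_COLORS = {
    "UNANNOTATED": "#BDBDBD",
    "REVIEW_NAME": "#E6A23C",
    "TRNA": "#4DB6AC",
    "GREEN": "#2E7D32",
    "RED": "#C62828",
    "BLUE": "#1565C0",
    "PURPLE": "#6A1B9A",
    "YELLOW": "#F9A825",
    "ORANGE": "#EF6C00",
    "NONE": "#757575",
}


@dataclass
class GenomeMap:
    """Static genome-map data: one block per feature, coloured by flag."""

    genome: str
    length: int
    blocks: list[dict]

    def to_json(self) -> str:
        return json.dumps(
            {"genome": self.genome, "length": self.length, "blocks": self.blocks},
            indent=2,
            sort_keys=True,
        )

    def to_svg(self, width: int = 1000, height: int = 60) -> str:
        scale = width / self.length
        rows = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
            f'<rect x="0" y="{height // 2 - 1}" width="{width}" height="2" fill="#444"/>',
        ]
        for b in self.blocks:
            color = FLAG_COLORS.get(b["flag"], "#757575")
            y = 8 if b["strand"] == "+" else height - 28
            if b["start"] <= b["stop"]:
                segs = [(b["start"], b["stop"])]
            else:  # origin-wrapping block drawn as two segments
                segs = [(b["start"], self.length), (0, b["stop"])]
            for s, e in segs:
                rows.append(
                    f'<rect x="{s * scale:.1f}" y="{y}" width="{max((e - s) * scale, 1):.1f}"'
                    f' height="20" fill="{color}"><title>{b["accession"]} {b["label"]}</title></rect>'
                )
        rows.append("</svg>")
        return "\n".join(rows)


def genome_map(store: Store, genome_name: str) -> Optional[GenomeMap]:
    """Genome-map data for rendering; None when the genome has >= 1000 features."""
    genome = store.get_genome(genome_name)  # raises NotFoundError if absent
    if len(genome.features) >= GENOME_MAP_MAX_FEATURES:
        return None
    blocks = []
    for f in genome.features:
        ann = store.get_annotation(f.accession)
        blocks.append(
            {
                "start": f.start,
                "stop": f.stop,
                "strand": f.strand,
                "kind": f.kind,
                "flag": ann.flag,
                "label": ann.label,
                "accession": f.accession,
            }
        )
    return GenomeMap(genome=genome_name, length=len(genome), blocks=blocks)
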