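"""Rule engine turning evidence summaries into label recommendations.

The engine encodes the conventional decision guide for manual functional
annotation as an ordered list of procedures P1..P12, evaluated first-match:

* P1   no usable evidence anywhere -> "hypothetical protein".
* P2   only nr significant, its own hits disagree -> disregard, hypothetical
       protein, flag for review.
* P3   only nr significant and self-consistent -> adopt the nr label but flag
       for review (nr curation is uneven).
* P4   domain search (rpsblast/CDD) significant, consistent, full coverage
       both ways -> functional label from the domain, or
       "<DOMAIN> domain-containing protein" for domains of unknown function.
* P5   domain hit covers the whole domain but only part of the query ->
       "<DOMAIN> domain-containing protein".
* P6   significant but mutually inconsistent domain hits -> same-interval
       conflicts resolve to the most significant domain; disjoint intervals
       mean a multi-domain protein and the most significant domain names it.
* P7   Swiss-Prot significant, consistent across databases, full-length
       agreement -> adopt the Swiss-Prot label verbatim.
* P8   significant evidence with a query/subject length mismatch or partial
       coverage -> adopt the top label but flag for review (possible wrong
       start codon, truncation, or shared domain only).
* P9   only moderate significance -> "putative "-prefixed label when the
       hits agree, otherwise hypothetical protein flagged for review.
* P10  the internal database is significant (alone or agreeing with the
       rest) -> reuse its label and flag so naming stays consistent.
* P11  HMM-HMM search (hhsearch) is the only significant evidence -> use a
       generalized form of the label ("cell death-related nuclease" ->
       "nuclease"), "putative "-prefixed when generalization loses detail.
* P12  two or more databases significant but mutually inconsistent -> take
       the most curated database's label and flag for review.

Exactly one procedure fires for any well-formed summary.  The engine only
suggests; nothing is written until :func:`apply_recommendation` is called
with an explicit accept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .config import Thresholds, DEFAULT_THRESHOLDS
from .errors import ConflictError, ValidationError
from .evidence import (
    CURATION_ORDER,
    DbEvidence,
    EvidenceSummary,
    consistent_across,
    normalize_label,
    _strip_internal_header,
)
from .store import Store

SP = ("blastp", "swissprot")
INTERNAL = ("blastp", "internal")
NR = ("blastp", "nr")
CDD = ("rpsblast", "cdd")
HH = ("hhsearch", "pdb")

_DUF = re.compile(r"\bDUF\d+\b", re.IGNORECASE)

# multiword functional heads restored after generalization
_SUBUNIT_HEADS = {("large", "subunit"), ("small", "subunit")}
_PAIR_HEADS = {("tail", "fiber"), ("tail", "spike"), ("base", "plate")}

PROCEDURES = tuple(f"P{i}" for i in range(1, 13))


@dataclass
class Recommendation:
    """Suggested label/flag for one annotation plus the audit trail."""

    accession: str
    procedure: str
    suggested_label: str
    suggested_flag: Optional[str]  # None = leave the current flag
    prepend_putative: bool
    rationale: str
    version: Optional[int] = None

    @property
    def final_label(self) -> str:
        label = self.suggested_label
        if self.prepend_putative and not label.lower().startswith("putative "):
            label = "putative " + label
        return label


def generalize_label(label: str) -> str:
    """Reduce a specific product name to its head functional noun.

    "cell death-related nuclease" -> "nuclease"; protected multiword heads
    like "large subunit" keep the word that qualifies them, so "terminase
    large subunit" is a fixed point.  A label with no functional content maps
    to "hypothetical protein".
    """
    tokens = normalize_label(label)
    if not tokens:
        return "hypothetical protein"
    if len(tokens) >= 2 and tuple(tokens[-2:]) in _SUBUNIT_HEADS:
        return " ".join(tokens[-3:] if len(tokens) >= 3 else tokens[-2:])
    if len(tokens) >= 2 and tuple(tokens[-2:]) in _PAIR_HEADS:
        return " ".join(tokens[-2:])
    return tokens[-1]


def _hit_label(ev: DbEvidence) -> str:
    if ev.top_hit is None:
        return ""
    return _strip_internal_header(ev.top_hit.subject_description).strip()


def _internal_label_flag(ev: DbEvidence) -> tuple[str, Optional[str]]:
    desc = ev.top_hit.subject_description if ev.top_hit else ""
    parts = desc.split("|", 2)
    if len(parts) == 3:
        return parts[2].strip(), parts[1].strip() or None
    return desc.strip(), None


def _domain_name(ev: DbEvidence) -> str:
    hit = ev.top_hit
    text = f"{hit.subject_id} {hit.subject_description}"
    m = _DUF.search(text)
    if m:
        return m.group(0).upper()
    desc = hit.subject_description.strip()
    return (desc.split(",", 1)[0].strip() or hit.subject_id) if desc else hit.subject_id


def _domain_functional_label(ev: DbEvidence) -> str:
    desc = ev.top_hit.subject_description.strip()
    if "," in desc:
        return desc.split(",", 1)[1].strip()
    return desc or ev.top_hit.subject_id


def recommend(
    summary: EvidenceSummary, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> Recommendation:
    """Run the decision guide over one evidence summary.

    Returns the first procedure whose situation matches, the label and flag
    it suggests, and a rationale enumerating every predicate that was
    evaluated together with the thresholds in force.
    """
    if summary.query_length <= 0:
        raise ValidationError("malformed summary: non-positive query length")

    ev = {key: summary.evidence(*key) for key in (SP, INTERNAL, NR, CDD, HH)}

    def sig(key) -> bool:
        return ev[key].significance == "significant"

    def moderate(key) -> bool:
        return ev[key].significance == "moderate"

    def perfect(key) -> bool:
        e = ev[key]
        return (
            e.length_similar
            and e.q_coverage_class == "all_most"
            and e.s_coverage_class == "all_most"
        )

    sig_dbs = [k for k in (INTERNAL, SP, CDD, HH, NR) if sig(k)]
    mod_dbs = [k for k in (INTERNAL, SP, CDD, HH, NR) if moderate(k)]
    across = consistent_across(summary, thresholds)

    predicates = {
        "present": sorted(f"{t}:{d}" for (t, d), e in ev.items() if e.present),
        "significant": sorted(f"{t}:{d}" for t, d in sig_dbs),
        "moderate": sorted(f"{t}:{d}" for t, d in mod_dbs),
        "consistent_across": across,
        **{
            f"consistent_within[{d}]": ev[(t, d)].consistent_within
            for t, d in (SP, INTERNAL, NR, CDD, HH)
            if ev[(t, d)].present
        },
    }

    def finish(
        procedure: str,
        label: str,
        note: str,
        flag: Optional[str] = None,
        putative: bool = False,
    ) -> Recommendation:
        lines = [f"{procedure}: {note}"]
        lines += [f"  {k} = {v}" for k, v in sorted(predicates.items())]
        lines.append(
            "  thresholds: "
            f"significant e<={thresholds.evalue_significant:g},"
            f" moderate e<={thresholds.evalue_moderate:g},"
            f" hh prob>={thresholds.hh_prob_significant:g}/{thresholds.hh_prob_moderate:g},"
            f" all/most cov>={thresholds.coverage_all_most:g},"
            f" some cov>={thresholds.coverage_some:g},"
            f" length similar>={thresholds.length_similar:g},"
            f" jaccard>={thresholds.consistency_jaccard:g}"
        )
        return Recommendation(
            accession=summary.accession,
            procedure=procedure,
            suggested_label=label or "hypothetical protein",
            suggested_flag=flag,
            prepend_putative=putative,
            rationale="\n".join(lines),
            version=summary.version,
        )

    # P1 -- no usable evidence
    if not sig_dbs and not mod_dbs:
        return finish("P1", "hypothetical protein", "no significant or moderate results in any database")

    only_nr_sig = sig_dbs == [NR]
    others_not_sig = not any(sig(k) for k in (SP, INTERNAL, CDD, HH))

    # P2/P3 -- nr is the only significant database
    if only_nr_sig and others_not_sig:
        if not ev[NR].consistent_within:
            return finish(
                "P2",
                "hypothetical protein",
                "only nr is significant and its hits disagree; results disregarded",
                flag="REVIEW_NAME",
            )
        return finish(
            "P3",
            _hit_label(ev[NR]),
            "only nr is significant; adopting its label pending reliability review",
            flag="REVIEW_NAME",
        )

    # P4/P5/P6 -- domain evidence leads
    cdd_leads = sig(CDD) and not any(sig(k) for k in (SP, INTERNAL, HH))
    if cdd_leads and ev[CDD].consistent_within:
        duf = _DUF.search(
            f"{ev[CDD].top_hit.subject_id} {ev[CDD].top_hit.subject_description}"
        )
        if ev[CDD].q_coverage_class == "all_most" and ev[CDD].s_coverage_class == "all_most":
            if duf:
                label = f"{_domain_name(ev[CDD])} domain-containing protein"
                note = "consistent full-coverage domain of unknown function"
            else:
                label = _domain_functional_label(ev[CDD])
                note = "consistent full-coverage functional domain; labelled by its function"
            return finish("P4", label, note)
        if ev[CDD].s_coverage_class == "all_most" and ev[CDD].q_coverage_class == "some":
            return finish(
                "P5",
                f"{_domain_name(ev[CDD])} domain-containing protein",
                "domain fully aligned but covers only part of the query",
            )
    if cdd_leads and not ev[CDD].consistent_within:
        top = ev[CDD].top_hit
        others = [
            h
            for h in ev[CDD].hits[1 : thresholds.consistency_top_k]
            if set(normalize_label(h.subject_description))
            != set(normalize_label(top.subject_description))
        ]
        overlapping = all(
            min(top.q_end, h.q_end) >= max(top.q_start, h.q_start) for h in others
        )
        name = _domain_name(ev[CDD])
        if overlapping:
            note = (
                "inconsistent domains over the same query interval;"
                " most significant domain names the protein"
            )
        else:
            note = (
                "inconsistent domains at disjoint query intervals (likely"
                " multi-domain protein); most significant domain names it"
            )
        return finish("P6", f"{name} domain-containing protein", note)

    # P7 -- Swiss-Prot leads
    if sig(SP) and not sig(INTERNAL) and across and perfect(SP):
        return finish(
            "P7",
            _hit_label(ev[SP]),
            "Swiss-Prot significant, consistent across databases, full-length"
            " agreement; label adopted verbatim",
        )

    # P8 -- length mismatch / partial coverage patterns
    if sig_dbs:
        best = next(k for k in CURATION_ORDER if k in sig_dbs)
        if not perfect(best):
            e = ev[best]
            reasons = []
            if not e.length_similar:
                reasons.append("query and subject lengths differ")
            if e.q_coverage_class != "all_most":
                reasons.append(
                    "alignment covers only part of the query (possible shared"
                    " domain or incorrect start codon)"
                )
            if e.s_coverage_class != "all_most":
                reasons.append(
                    "alignment covers only part of the subject (query may be"
                    " truncated or its start codon incorrect)"
                )
            label = (
                _internal_label_flag(e)[0] if best == INTERNAL else _hit_label(e)
            )
            return finish(
                "P8",
                label,
                "significant evidence with partial coverage: " + "; ".join(reasons),
                flag="REVIEW_NAME",
            )

    # P9 -- only moderate significance anywhere
    if not sig_dbs and mod_dbs:
        best = next(k for k in CURATION_ORDER if k in mod_dbs)
        if len(mod_dbs) > 1:
            agree = across
        else:
            agree = ev[best].consistent_within
        if agree:
            label = (
                _internal_label_flag(ev[best])[0]
                if best == INTERNAL
                else _hit_label(ev[best])
            )
            return finish(
                "P9",
                label,
                "only moderate significance without cross-database confirmation;"
                " label prefixed with 'putative'",
                putative=True,
            )
        return finish(
            "P9",
            "hypothetical protein",
            "only moderate significance and the hits disagree",
            flag="REVIEW_NAME",
        )

    # P10 -- internal database governs naming
    if sig(INTERNAL) and (len(sig_dbs) == 1 or across):
        label, flag = _internal_label_flag(ev[INTERNAL])
        return finish(
            "P10",
            label,
            "internal database significant; reusing its label and flag keeps"
            " naming conventions consistent",
            flag=flag,
        )

    # P11 -- hhsearch is the only significant tool
    if sig(HH) and not any(sig(k) for k in (SP, INTERNAL, CDD)):
        label = _hit_label(ev[HH])
        general = generalize_label(label)
        lossy = normalize_label(general) != normalize_label(label)
        return finish(
            "P11",
            general,
            "only HMM-HMM evidence; label generalized to avoid over-specific"
            " annotation" + (" (generalization is lossy)" if lossy else ""),
            putative=lossy,
        )

    # P12 -- significant but inconsistent across databases
    if sig_dbs and not across:
        best = next(k for k in CURATION_ORDER if k in sig_dbs)
        label = (
            _internal_label_flag(ev[best])[0] if best == INTERNAL else _hit_label(ev[best])
        )
        return finish(
            "P12",
            label,
            "significant results disagree across databases; most curated"
            f" database ({best[1]}) names the protein pending investigation",
            flag="REVIEW_NAME",
        )

    # Residual significant-but-unclassified evidence; reviewed like an
    # inconsistency so no summary goes unhandled.
    best = next(k for k in CURATION_ORDER if k in sig_dbs)
    label = _internal_label_flag(ev[best])[0] if best == INTERNAL else _hit_label(ev[best])
    return finish(
        "P12",
        label,
        "significant evidence did not match a more specific situation;"
        " flagged for manual review",
        flag="REVIEW_NAME",
    )


def apply_recommendation(
    store: Store, recommendation: Recommendation, user: str, accept: bool = True
):
    """Write an accepted recommendation through the normal edit path.

    Rejecting records nothing.  If the annotation was edited after the
    summary the recommendation was built from, a :class:`ConflictError` is
    raised instead of silently overwriting.  When no rule dictated a flag,
    accepting clears UNANNOTATED to NONE (the protein is now annotated).
    """
    if not accept:
        return None
    current = store.get_annotation(recommendation.accession)
    if recommendation.version is not None:
        if len(store.get_history(recommendation.accession)) != recommendation.version:
            raise ConflictError(
                f"annotation {recommendation.accession} changed since the"
                " evidence summary was built"
            )
    changes = {"label": recommendation.final_label}
    if recommendation.suggested_flag is not None:
        changes["flag"] = recommendation.suggested_flag
    elif current.flag == "UNANNOTATED":
        changes["flag"] = "NONE"
    return store.update_annotation(recommendation.accession, changes, user)


def recommendations_to_tsv(store: Store, recommendations: list[Recommendation]) -> str:
    """Review sheet: accession, current label, suggestion, procedure, rationale."""
    rows = ["accession\tcurrent_label\tsuggested_label\tprocedure\trationale"]
    for rec in recommendations:
        current = store.get_annotation(rec.accession).label
        rationale = rec.rationale.replace("\t", " ").replace("\n", " | ")
        rows.append(
            f"{rec.accession}\t{current}\t{rec.final_label}\t{rec.procedure}\t{rationale}"
        )
    return "\n".join(rows) + "\n"
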