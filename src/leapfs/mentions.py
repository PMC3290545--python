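"""Residue and point-mutation mention extraction from biomedical text.

Patterns are built compositionally from sub-expressions for amino-acid
names (full name, 3-letter, 1-letter), sequence positions, connectors
(space, hyphen, en/em dash) and mutation linkers (arrows, "mutated to"
phrasings).  Every match is normalized to the wild-type 3-letter code
plus the position, with an extra mutant code for mutation mentions.

Two operating modes exist.  The default *compat* mode reproduces the
documented behaviour of the original extraction system, including two
known over-generations: a full amino-acid name followed by a
parenthesized number ("tyrosine (6)") is read as a residue mention, and
a capital letter trailing a 3-letter mention ("Cys105L") is read as a
mutation even though such letters sometimes denote a chain.  ``strict``
mode suppresses both pattern classes.

A bare amino-acid name with no position ("Glycine") never yields a
mention, and 1-letter codes are only recognized inside the compact
mutation form (e.g. "G146A"), where the surrounding digits provide the
positional context.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from ._aa import NAME_TO_THREE, ONE_TO_THREE, STANDARD_CODES

logger = logging.getLogger(__name__)

MAX_POSITION = 99999

# --- sub-expressions ------------------------------------------------------

_FULL_NAMES = sorted(NAME_TO_THREE, key=len, reverse=True)
FULL = r"(?:" + "|".join(n.replace(" ", r"\s") for n in _FULL_NAMES) + r")"
AA3 = r"(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val)"
AA1 = r"[ACDEFGHIKLMNPQRSTVWY]"
POS = r"(?:[1-9]\d{0,4})"
#: connectors between a name and its position: nothing, space, hyphen,
#: en dash, em dash (U+2014)
CONN = "[-–— ]?"
#: mutation linkers: ASCII or Unicode arrows (U+2192), or a slash
ARROW = "(?:→|-+>|/)"
_B = r"(?<![A-Za-z0-9])"   # left boundary
_E = r"(?![A-Za-z0-9])"    # right boundary

_VERB = r"(?:mutated|substituted|replaced|changed|converted|exchanged)"
_PREP = r"(?:to|into|by|with|for)"


def _c(pattern: str) -> re.Pattern:
    return re.compile(pattern, re.IGNORECASE)


# Ordered pattern table: (pattern, kind, compat_only).  Earlier entries
# win when spans overlap, so mutations precede plain residue mentions.
_PATTERNS: list[tuple[re.Pattern, str, bool]] = [
    # His-554 mutated to glutamine / Asp 104 was replaced by Ala
    (_c(rf"{_B}(?P<wt>{FULL}|{AA3}){CONN}(?P<pos>{POS})\s+(?:residue\s+)?(?:was\s+|is\s+|were\s+)?"
        rf"{_VERB}\s+{_PREP}\s+(?:an?\s+)?(?P<mut>{FULL}|{AA3}){_E}"),
     "mut_linguistic", False),
    # mutation of Asp104 to alanine
    (_c(rf"{_B}(?:mutation|substitution|replacement)\s+of\s+(?P<wt>{FULL}|{AA3}){CONN}"
        rf"(?P<pos>{POS})\s+{_PREP}\s+(?:an?\s+)?(?P<mut>{FULL}|{AA3}){_E}"),
     "mut_linguistic", False),
    # Asp104→Ala, His554->Gln
    (_c(rf"{_B}(?P<wt>{FULL}|{AA3}){CONN}(?P<pos>{POS})\s*{ARROW}\s*(?P<mut>{FULL}|{AA3}){_E}"),
     "mut_arrow", False),
    # Gly146Ala, Asp-104-Ala
    (_c(rf"{_B}(?P<wt>{AA3}){CONN}(?P<pos>{POS}){CONN}(?P<mut>{AA3}){_E}"),
     "mut_3letter", False),
    # G146A (1-letter codes are case-sensitive)
    (re.compile(rf"{_B}(?P<wt>{AA1})(?P<pos>{POS})(?P<mut>{AA1}){_E}"),
     "mut_1letter", False),
    # Cys105L: trailing capital read as a mutant code (compat quirk);
    # case-sensitive so only title-case 3-letter mentions trigger it
    (re.compile(rf"{_B}(?P<wt>{AA3}){CONN}(?P<pos>{POS})(?P<mut>{AA1}){_E}"),
     "mut_trailing", True),
    # cysteines at positions 6, 24, and 393
    (_c(rf"{_B}(?P<aa>{FULL})s?\s+(?:residues?\s+)?at\s+positions?\s+"
        rf"(?P<list>{POS}(?:\s*,\s*{POS})*(?:\s*,?\s*(?:and|or)\s+{POS})?)"),
     "enumeration", False),
    # tyrosine (6): parenthesized position (compat quirk)
    (_c(rf"{_B}(?P<aa>{FULL})\s*\(\s*(?P<pos>{POS})\s*\){_E}"),
     "paren_position", True),
    # Asp104, Asp-104, aspartate 104, His—554
    (_c(rf"{_B}(?P<aa>{FULL}|{AA3}){CONN}(?P<pos>{POS}){_E}"),
     "residue", False),
]

_POS_RE = re.compile(POS)


@dataclass(frozen=True)
class NormalizedMention:
    wt_code: str
    position: int
    mut_code: str | None
    span: tuple[int, int]
    source: str | None = None

    @property
    def is_mutation(self) -> bool:
        return self.mut_code is not None

    def canonical_form(self) -> str:
        """A text form that re-extracts to the same normalized record."""
        wt = self.wt_code.capitalize()
        if self.mut_code is None:
            return f"{wt}{self.position}"
        return f"{wt}{self.position}{self.mut_code.capitalize()}"

    def key(self) -> tuple:
        return (self.wt_code, self.position, self.mut_code)


def _norm_aa(token: str) -> str | None:
    """Any surface form -> 3-letter code, or None if unrecognized."""
    t = re.sub(r"\s+", " ", token.strip())
    if len(t) == 1:
        return ONE_TO_THREE.get(t.upper())
    if t.upper() in STANDARD_CODES:
        return t.upper()
    return NAME_TO_THREE.get(t.lower())


def extract_mentions(
    text: str,
    source: str | None = None,
    strict: bool = False,
) -> list[NormalizedMention]:
    """All normalized residue/mutation mentions in ``text``.

    Patterns are applied in priority order (mutations before plain
    residue mentions); a later match that overlaps an accepted span is
    discarded.  Results are sorted by span start.
    """
    taken: list[tuple[int, int]] = []
    found: list[NormalizedMention] = []

    def free(start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in taken)

    for pattern, kind, compat_only in _PATTERNS:
        if strict and compat_only:
            continue
        for m in pattern.finditer(text):
            if not free(*m.span()):
                continue
            if kind == "enumeration":
                code = _norm_aa(m.group("aa"))
                if code is None:
                    continue
                any_ok = False
                for pm in _POS_RE.finditer(m.group("list")):
                    pos = int(pm.group())
                    start = m.start("list") + pm.start()
                    end = m.start("list") + pm.end()
                    found.append(NormalizedMention(code, pos, None, (m.start(), end), source))
                    any_ok = True
                if any_ok:
                    taken.append(m.span())
                continue
            if kind in ("residue", "paren_position"):
                code = _norm_aa(m.group("aa"))
                if code is None:
                    continue
                pos = int(m.group("pos"))
                if pos > MAX_POSITION:
                    continue
                found.append(NormalizedMention(code, pos, None, m.span(), source))
                taken.append(m.span())
                continue
            # mutation kinds
            wt = _norm_aa(m.group("wt"))
            mut = _norm_aa(m.group("mut"))
            pos = int(m.group("pos"))
            if wt is None or mut is None or wt == mut or pos > MAX_POSITION:
                continue
            found.append(NormalizedMention(wt, pos, mut, m.span(), source))
            taken.append(m.span())

    found.sort(key=lambda x: x.span)
    return found


# --- evaluation -----------------------------------------------------------

@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision_defined: bool = True
    recall_defined: bool = True

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def percent(self) -> tuple[int, int]:
        """(precision, recall) rounded to whole percents."""
        return round(100 * self.precision), round(100 * self.recall)


def prf_from_counts(n_extracted: int, n_correct: int, n_gold: int) -> EvalResult:
    """Evaluation arithmetic from aggregate counts.

    ``n_extracted`` system outputs of which ``n_correct`` match the
    ``n_gold`` reference annotations: TP = correct, FP = extracted -
    correct, FN = gold - correct.
    """
    if not 0 <= n_correct <= min(n_extracted, n_gold):
        raise ValueError("inconsistent counts")
    return EvalResult(tp=n_correct, fp=n_extracted - n_correct, fn=n_gold - n_correct)


def _match_key(m: NormalizedMention, span_mode: bool) -> tuple:
    base = (m.source, m.wt_code, m.position, m.mut_code)
    return base + (m.span,) if span_mode else base


def evaluate(
    gold: list[NormalizedMention],
    pred: list[NormalizedMention],
    span_mode: bool = False,
) -> EvalResult:
    """Micro TP/FP/FN between normalized gold and system mentions.

    A residue match requires the 3-letter code and position to agree; a
    mutation match additionally requires the mutant code.  With
    ``span_mode`` the character span must agree too (used for corpora
    annotated with exact offsets).  Duplicate gold entries under the
    matching key are counted once, with a warning.
    """
    gold_keys: dict[tuple, int] = {}
    for g in gold:
        k = _match_key(g, span_mode)
        if k in gold_keys:
            logger.warning("duplicate gold annotation %r counted once", k)
        gold_keys[k] = 1
    tp = fp = 0
    seen_pred: set[tuple] = set()
    for p in pred:
        k = _match_key(p, span_mode)
        if k in seen_pred:
            continue  # duplicate system output, count once
        seen_pred.add(k)
        if gold_keys.pop(k, None):
            tp += 1
        else:
            fp += 1
    fn = len(gold_keys)
    res = EvalResult(tp=tp, fp=fp, fn=fn)
    if tp + fp == 0 and fn > 0:
        res.precision_defined = False
    if tp + fn == 0:
        res.recall_defined = False
    return res


def corpus_report(
    gold_by_doc: dict[str, list[NormalizedMention]],
    pred_by_doc: dict[str, list[NormalizedMention]],
    span_mode: bool = False,
) -> EvalResult:
    """Micro-averaged evaluation over a corpus of documents."""
    if not gold_by_doc:
        raise ValueError("empty corpus")
    missing = set(gold_by_doc) ^ set(pred_by_doc)
    if missing:
        raise ValueError(f"document id mismatch between gold and system: {sorted(missing)}")
    tp = fp = fn = 0
    for doc in gold_by_doc:
        r = evaluate(gold_by_doc[doc], pred_by_doc[doc], span_mode=span_mode)
        tp, fp, fn = tp + r.tp, fp + r.fp, fn + r.fn
    return EvalResult(tp=tp, fp=fp, fn=fn)


# --- gold-corpus I/O ------------------------------------------------------

_WNM_RE = re.compile(rf"^({AA1})(\d+)({AA1})$")
_XXX_RE = re.compile(rf"^({AA3})(\d+)({AA3})?$", re.IGNORECASE)


def parse_normalized_token(token: str) -> tuple[str, int, str | None] | None:
    """Parse "W123M" / "Trp123Met" / "Trp123" into (wt, pos, mut)."""
    m = _WNM_RE.match(token)
    if m:
        return (ONE_TO_THREE[m.group(1)], int(m.group(2)), ONE_TO_THREE[m.group(3)])
    m = _XXX_RE.match(token)
    if m:
        mut = m.group(3).upper() if m.group(3) else None
        return (m.group(1).upper(), int(m.group(2)), mut)
    return None


def read_gold_mentions(path, span: bool = False) -> dict[str, list[NormalizedMention]]:
    """Read a gold-mention table.

    Without spans (MutationFinder-style): tab-separated ``doc_id`` then
    one normalized token (e.g. ``W123M`` or ``Asp104``) per column.
    With spans: ``doc_id  start  end  wt3  pos  mut3-or-blank`` rows.
    """
    out: dict[str, list[NormalizedMention]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            doc = cols[0]
            out.setdefault(doc, [])
            if span:
                start, end, wt, pos, mut = cols[1:6]
                out[doc].append(NormalizedMention(
                    wt.upper(), int(pos), mut.upper() or None,
                    (int(start), int(end)), doc))
            else:
                for token in cols[1:]:
                    parsed = parse_normalized_token(token.strip())
                    if parsed is None:
                        logger.warning("unparseable gold token %r in %s", token, doc)
                        continue
                    wt, pos, mut = parsed
                    out[doc].append(NormalizedMention(wt, pos, mut, (0, 0), doc))
    return out
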