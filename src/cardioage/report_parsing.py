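"""Rule-based extraction of key metrics from structured coronary CTA reports.

A structured CTA report carries three key metrics: the coronary artery
calcium (CAC) score in Agatston units, the CAD-RADS stenosis-severity
category, and left-ventricular function (LVEF, optionally EDV/ESV).  This
module extracts them deterministically from German- or English-language
report text with a fixed lexicon, records character spans for audit, and
classifies unparseable reports into a typed failure taxonomy
(``missing_cac``, ``missing_cadrads``, ``ambiguous_phrasing``,
``missing_function``, ``malformed_number``).

A report parses successfully iff all three key metrics are found; the
failure reason reported is the first missing metric in the fixed order
CAC -> CAD-RADS -> function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional

from .errors import InputError

__all__ = [
    "KeyMetrics",
    "ParseResult",
    "AnatomyFlags",
    "CADRADS_CATEGORIES",
    "parse_report",
    "extract_cac",
    "extract_cadrads",
    "extract_anatomy_flags",
    "extract_function",
    "extract_extracoronary",
    "detect_locale",
    "cadrads_rank",
]

#: CAD-RADS categories in increasing severity order.
CADRADS_CATEGORIES: tuple[str, ...] = ("0", "1", "2", "3", "4a", "4b", "5")

_CADRADS_RANK = {c: i for i, c in enumerate(CADRADS_CATEGORIES)}

VESSELS: tuple[str, ...] = ("LAD", "RCA", "CX")

EXTRACORONARY_FINDINGS: tuple[str, ...] = ("aortic_ectasia", "aortic_aneurysm", "other")


def cadrads_rank(category: str) -> int:
    """Position of *category* in the severity order 0 < 1 < 2 < 3 < 4a < 4b < 5."""
    try:
        return _CADRADS_RANK[category]
    except KeyError:
        raise ValueError(f"unknown CAD-RADS category: {category!r}") from None


@dataclass(frozen=True)
class KeyMetrics:
    """Structured content of one coronary CTA report.

    Parameters
    ----------
    cac_au
        Coronary artery calcium score in Agatston units (>= 0).
    cadrads
        CAD-RADS category, one of ``"0" "1" "2" "3" "4a" "4b" "5"``.
    lvef_percent
        Left-ventricular ejection fraction in percent, in (0, 100].
    vessel_over50
        Major epicardial vessels (subset of LAD/RCA/CX) with a stenosis
        whose band lower bound is >= 50%.
    proximal_lad_over70
        Proximal LAD segment stenosis >= 70% (high-risk anatomy).
    soft_plaque_rca_cx_only
        Non-calcified plaque confined to RCA and/or CX with no >= 50%
        LAD lesion.
    hrp_present
        Any high-risk plaque feature (napkin-ring sign, spotty
        calcification, positive remodeling, low-attenuation plaque).
    edv_ml, esv_ml
        LV end-diastolic / end-systolic volume in mL, optional.
    extracoronary_findings
        Coded vascular-aging findings outside the coronaries.
    """

    cac_au: float
    cadrads: str
    lvef_percent: float
    vessel_over50: frozenset = frozenset()
    proximal_lad_over70: bool = False
    soft_plaque_rca_cx_only: bool = False
    hrp_present: bool = False
    edv_ml: Optional[float] = None
    esv_ml: Optional[float] = None
    extracoronary_findings: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "vessel_over50", frozenset(self.vessel_over50))
        object.__setattr__(
            self, "extracoronary_findings", frozenset(self.extracoronary_findings)
        )

    def validate(self) -> "KeyMetrics":
        """Check the domain invariants; return ``self`` or raise ``ValueError``."""
        if not self.cac_au >= 0:
            raise ValueError(f"cac_au must be >= 0, got {self.cac_au}")
        cadrads_rank(self.cadrads)
        if not 0 < self.lvef_percent <= 100:
            raise ValueError(f"lvef_percent must be in (0, 100], got {self.lvef_percent}")
        if not self.vessel_over50 <= set(VESSELS):
            raise ValueError(f"unknown vessels: {self.vessel_over50 - set(VESSELS)}")
        if not self.extracoronary_findings <= set(EXTRACORONARY_FINDINGS):
            raise ValueError(
                f"unknown findings: {self.extracoronary_findings - set(EXTRACORONARY_FINDINGS)}"
            )
        if self.cadrads in ("4a", "4b", "5"):
            if not self.vessel_over50 and not self.proximal_lad_over70:
                raise ValueError(
                    "CAD-RADS >= 4a requires a >=50% vessel or a proximal LAD lesion"
                )
        if self.soft_plaque_rca_cx_only and "LAD" in self.vessel_over50:
            raise ValueError("soft_plaque_rca_cx_only excludes a >=50% LAD lesion")
        if self.proximal_lad_over70 and "LAD" not in self.vessel_over50:
            raise ValueError("proximal LAD >=70% implies LAD in vessel_over50")
        if self.edv_ml is not None and self.edv_ml < 0:
            raise ValueError("edv_ml must be >= 0")
        if self.esv_ml is not None and self.esv_ml < 0:
            raise ValueError("esv_ml must be >= 0")
        if self.edv_ml is not None and self.esv_ml is not None:
            if not self.esv_ml < self.edv_ml:
                raise ValueError("esv_ml must be < edv_ml when both present")
        return self


class AnatomyFlags(NamedTuple):
    vessel_over50: frozenset
    proximal_lad_over70: bool
    soft_plaque_rca_cx_only: bool
    hrp_present: bool


@dataclass(frozen=True)
class ParseResult:
    """Outcome of parsing one report: either metrics or a typed failure."""

    outcome: str  # "parsed" | "failed"
    metrics: Optional[KeyMetrics] = None
    failure_reason: Optional[str] = None
    matched_spans: tuple = field(default_factory=tuple)
    locale: str = "en"

    @property
    def parsed(self) -> bool:
        return self.outcome == "parsed"


class _Malformed(Exception):
    """Internal: a number token was present but not parseable."""


class _Ambiguous(Exception):
    """Internal: a CAD-RADS token was present but its category was not."""


# ---------------------------------------------------------------------------
# number handling

_GERMAN_MARKERS = (
    "kalkscore", "befund", "keine", "stenose", "einengung", "verkalkung",
    "herz", "linksventrikul", "unauff", "aorta ascendens", "ektasie",
    "koronararterien", "gef",
)
_ENGLISH_MARKERS = (
    "calcium score", "findings", "stenosis", "no significant",
    "left ventricular", "ascending aorta", "coronary arteries", "report",
    "ectasia", "vessel",
)


def detect_locale(text: str) -> str:
    """Keyword-voting locale detection; ties resolve to English."""
    low = text.lower()
    de = sum(low.count(m) for m in _GERMAN_MARKERS)
    en = sum(low.count(m) for m in _ENGLISH_MARKERS)
    return "de" if de > en else "en"


def _parse_number(token: str, locale: str) -> float:
    """Normalize a numeric token that may use decimal comma and thousands
    separators ('1.204,5' under de -> 1204.5; '1,204.5' under en -> 1204.5)."""
    token = token.strip().rstrip(".,")
    if not token:
        raise _Malformed(token)
    has_comma, has_dot = "," in token, "." in token
    if has_comma and has_dot:
        # the rightmost separator is the decimal mark
        if token.rfind(",") > token.rfind("."):
            token = token.replace(".", "").replace(",", ".")
        else:
            token = token.replace(",", "")
    elif has_comma:
        parts = token.split(",")
        if len(parts) == 2 and (locale == "de" or len(parts[1]) != 3):
            token = token.replace(",", ".")
        else:
            token = token.replace(",", "")
    elif has_dot:
        parts = token.split(".")
        if locale == "de" and all(len(p) == 3 for p in parts[1:]) and len(parts) > 1 and parts[1:]:
            # German thousands grouping: 24.328 -> 24328
            if len(parts[0]) <= 3 and len(parts) > 1 and len(parts[-1]) == 3:
                token = token.replace(".", "")
        # otherwise a decimal point, leave as is
    try:
        return float(token)
    except ValueError:
        raise _Malformed(token) from None


# ---------------------------------------------------------------------------
# clause iteration

_CLAUSE_SPLIT = re.compile(r"[.;\n](?!\d)")


def _iter_clauses(text: str) -> Iterator[tuple[str, int]]:
    """Yield (clause, start_offset) split on sentence enders and newlines.

    The split ignores '.' directly followed by a digit so decimal points
    and German thousands separators survive.
    """
    start = 0
    for m in _CLAUSE_SPLIT.finditer(text):
        yield text[start : m.start()], start
        start = m.end()
    if start < len(text):
        yield text[start:], start


_NEGATORS = ("no ", "not ", "without ", "keine ", "kein ", "ohne ", "ausschluss ")


def _negated(clause_low: str, pos: int) -> bool:
    """True when a negation token precedes *pos* within the clause."""
    prefix = clause_low[:pos]
    return any(n in prefix or prefix.startswith(n.strip()) for n in _NEGATORS)


# ---------------------------------------------------------------------------
# CAC

_CAC_ANCHOR = re.compile(
    r"(?:agatston|kalkscore|calcium[\s-]?score|kalziumscore|\bCAC\b)",
    re.IGNORECASE,
)
_NUMBER = re.compile(r"\d[\d.,]*")


def _extract_cac(text: str, locale: str) -> Optional[tuple[float, tuple[int, int]]]:
    m = _CAC_ANCHOR.search(text)
    if m is None:
        return None
    # first number within the calcium-score scope (same line / 60 chars)
    scope_end = min(len(text), m.end() + 60)
    nl = text.find("\n", m.end())
    if nl != -1:
        scope_end = min(scope_end, nl)
    num = _NUMBER.search(text, m.end(), scope_end)
    if num is None:
        return None
    value = _parse_number(num.group(), locale)
    if value < 0:
        raise _Malformed(num.group())
    return value, (num.start(), num.end())


def extract_cac(text: str, locale: str = "en") -> Optional[float]:
    """CAC score in Agatston units, or ``None`` when no calcium-score
    section is found.  Accepts decimal comma and thousands separators."""
    got = _extract_cac(text, locale)
    return None if got is None else got[0]


# ---------------------------------------------------------------------------
# CAD-RADS

_CADRADS_TOKEN = re.compile(r"CAD[\s-]?RADS", re.IGNORECASE)
_CADRADS_CAT = re.compile(r"^[\s:™]*(?:2\.0\s*)?(?:kategorie\s*|category\s*)?([0-5][ab]?)", re.IGNORECASE)
_STENOSIS_SYNONYMS = ("einengung", "verengung", "lumeneinengung", "narrowing")


def _extract_cadrads(text: str) -> Optional[tuple[str, tuple[int, int]]]:
    best: Optional[tuple[str, tuple[int, int]]] = None
    n_tokens = 0
    for tok in _CADRADS_TOKEN.finditer(text):
        n_tokens += 1
        m = _CADRADS_CAT.match(text[tok.end() : tok.end() + 24])
        if m is None:
            continue
        cat = m.group(1).lower()
        if cat not in _CADRADS_RANK:
            continue
        span = (tok.end() + m.start(1), tok.end() + m.end(1))
        if best is None or cadrads_rank(cat) > cadrads_rank(best[0]):
            best = (cat, span)
    if best is None:
        if n_tokens:
            raise _Ambiguous("CAD-RADS token without a readable category")
        return None
    return best


def extract_cadrads(text: str) -> Optional[str]:
    """Patient-level CAD-RADS category: the maximum over all tokens in the
    text, or ``None`` when no token is present.  A token with no readable
    category raises ``ValueError`` (ambiguous phrasing)."""
    try:
        got = _extract_cadrads(text)
    except _Ambiguous as exc:
        raise ValueError(str(exc)) from None
    return None if got is None else got[0]


# ---------------------------------------------------------------------------
# anatomy flags

_VESSEL_PATTERNS = {
    "LAD": re.compile(r"\bLAD\b|\bRIVA\b", re.IGNORECASE),
    "RCA": re.compile(r"\bRCA\b", re.IGNORECASE),
    "CX": re.compile(r"\bR?CX\b|circumflex", re.IGNORECASE),
}
_PCT_BAND = re.compile(r"(\d{1,3}(?:[.,]\d)?)\s*[-–]\s*\d{1,3}(?:[.,]\d)?\s*%")
_PCT_SINGLE = re.compile(r"([><≥≤]?)\s*(\d{1,3}(?:[.,]\d)?)\s*%")
_OCCLUSION = re.compile(
    r"occlu|verschluss|verschlossen|okklu", re.IGNORECASE
)
_SOFT_PLAQUE = re.compile(
    r"non[\s-]?calcified|soft\s+plaque|nicht[\s-]?verkalkt|nichtkalzifiziert|"
    r"weichplaque|weiche[rn]?\s+plaque",
    re.IGNORECASE,
)
_PROXIMAL = re.compile(r"proximal", re.IGNORECASE)
_HRP = re.compile(
    r"high[\s-]?risk\s+plaque|hochrisiko|napkin[\s-]?ring|"
    r"spotty\s+calcification|punktförmige\s+verkalkung|"
    r"positive[s]?\s+remodel|low[\s-]?attenuation\s+plaque",
    re.IGNORECASE,
)


def _clause_stenosis_pct(clause: str) -> Optional[float]:
    """Largest stenosis severity stated in the clause; bands count by
    their lower bound, occlusion wording counts as 100."""
    best: Optional[float] = None
    for m in _PCT_BAND.finditer(clause):
        v = float(m.group(1).replace(",", "."))
        best = v if best is None else max(best, v)
    stripped = _PCT_BAND.sub(" ", clause)
    for m in _PCT_SINGLE.finditer(stripped):
        v = float(m.group(2).replace(",", "."))
        best = v if best is None else max(best, v)
    if _OCCLUSION.search(clause):
        best = 100.0
    return best


def _extract_anatomy(text: str, locale: str) -> tuple[AnatomyFlags, list]:
    vessel_over50: set[str] = set()
    soft_vessels: set[str] = set()
    proximal_lad = False
    hrp = False
    spans: list[tuple[str, tuple[int, int]]] = []

    for clause, off in _iter_clauses(text):
        low = clause.lower()
        vessels = [v for v, pat in _VESSEL_PATTERNS.items() if pat.search(clause)]
        if vessels:
            pct = _clause_stenosis_pct(clause)
            if pct is not None and pct >= 50 and not _negated(low, len(low)):
                for v in vessels:
                    if v not in vessel_over50:
                        vessel_over50.add(v)
                        vm = _VESSEL_PATTERNS[v].search(clause)
                        spans.append(("vessel_over50", (off + vm.start(), off + vm.end())))
                if "LAD" in vessels and _PROXIMAL.search(clause) and pct >= 70:
                    proximal_lad = True
                    spans.append(("proximal_lad_over70", (off, off + len(clause))))
            sp = _SOFT_PLAQUE.search(clause)
            if sp is not None and not _negated(low, sp.start()):
                soft_vessels.update(vessels)
        m = _HRP.search(clause)
        if m is not None and not _negated(low, m.start()):
            hrp = True
            spans.append(("hrp_present", (off + m.start(), off + m.end())))

    soft_only = bool(soft_vessels) and soft_vessels <= {"RCA", "CX"} and "LAD" not in vessel_over50
    return AnatomyFlags(frozenset(vessel_over50), proximal_lad, soft_only, hrp), spans


def extract_anatomy_flags(text: str, locale: str = "en") -> AnatomyFlags:
    """High-risk coronary anatomy flags from the per-vessel narrative.

    A vessel enters ``vessel_over50`` when a clause naming it states a
    stenosis whose band lower bound is >= 50% (occlusion wording counts as
    100%); a proximal-LAD clause with >= 70% sets ``proximal_lad_over70``;
    non-calcified-plaque wording confined to RCA/CX with no >=50% LAD
    lesion sets ``soft_plaque_rca_cx_only``; the high-risk-plaque lexicon
    (negation-guarded) sets ``hrp_present``.
    """
    flags, _ = _extract_anatomy(text, locale)
    return flags


# ---------------------------------------------------------------------------
# LV function

_LVEF = re.compile(r"\b(?:LV)?EF\s*[:\s]\s*(\d{1,3}(?:[.,]\d)?)\s*%", re.IGNORECASE)
_EDV = re.compile(r"EDV\s*[:\s]?\s*(\d[\d.,]*)\s*ml", re.IGNORECASE)
_ESV = re.compile(r"ESV\s*[:\s]?\s*(\d[\d.,]*)\s*ml", re.IGNORECASE)


def _extract_function(
    text: str, locale: str
) -> tuple[Optional[float], Optional[float], Optional[float], list]:
    spans = []
    lvef = edv = esv = None
    m = _LVEF.search(text)
    if m:
        lvef = _parse_number(m.group(1), locale)
        spans.append(("lvef_percent", (m.start(1), m.end(1))))
    m = _EDV.search(text)
    if m:
        edv = _parse_number(m.group(1), locale)
        spans.append(("edv_ml", (m.start(1), m.end(1))))
    m = _ESV.search(text)
    if m:
        esv = _parse_number(m.group(1), locale)
        spans.append(("esv_ml", (m.start(1), m.end(1))))
    return lvef, edv, esv, spans


def extract_function(text: str, locale: str = "en"):
    """``(lvef_percent, edv_ml, esv_ml)`` — LVEF from an ``LVEF``/``EF``
    token with percent; volumes optional."""
    lvef, edv, esv, _ = _extract_function(text, locale)
    return lvef, edv, esv


# ---------------------------------------------------------------------------
# extracoronary findings

_EXTRACORONARY = {
    "aortic_ectasia": re.compile(r"ectasia|ektasie", re.IGNORECASE),
    "aortic_aneurysm": re.compile(r"aneurysm", re.IGNORECASE),
    "other": re.compile(
        r"pulmonary nodule|rundherd|pleural effusion|pleuraerguss|"
        r"atherosclerosis of the descending aorta|"
        r"atherosklerose der aorta descendens",
        re.IGNORECASE,
    ),
}


def extract_extracoronary(text: str, locale: str = "en") -> frozenset:
    """Coded extracoronary vascular-aging findings (negation-guarded)."""
    found = set()
    for clause, _off in _iter_clauses(text):
        low = clause.lower()
        for code, pat in _EXTRACORONARY.items():
            m = pat.search(clause)
            if m is not None and not _negated(low, m.start()):
                found.add(code)
    return frozenset(found)


# ---------------------------------------------------------------------------
# top-level parse

def parse_report(text: str, locale: str = "auto") -> ParseResult:
    """Parse one CTA report into :class:`KeyMetrics` or a typed failure.

    Parameters
    ----------
    text
        UTF-8 report text (non-empty).
    locale
        ``"de"``, ``"en"`` or ``"auto"`` (keyword-voting detection).

    Returns
    -------
    ParseResult
        ``outcome="parsed"`` with metrics iff all three key metrics (CAC,
        CAD-RADS, LVEF) were found; otherwise ``outcome="failed"`` with
        the first missing metric's reason in the order CAC -> CAD-RADS ->
        function.  ``matched_spans`` reference substrings of *text*.

    Raises
    ------
    InputError
        On empty or whitespace-only text (distinct from a parse failure).
    """
    if not text or not text.strip():
        raise InputError("empty report text")
    if locale == "auto":
        locale = detect_locale(text)
    elif locale not in ("de", "en"):
        raise InputError(f"unknown locale hint: {locale!r}")

    spans: list[tuple[str, tuple[int, int]]] = []

    def fail(reason: str) -> ParseResult:
        return ParseResult(
            outcome="failed",
            failure_reason=reason,
            matched_spans=tuple(spans),
            locale=locale,
        )

    try:
        cac = _extract_cac(text, locale)
    except _Malformed:
        return fail("malformed_number")
    if cac is None:
        return fail("missing_cac")
    spans.append(("cac_au", cac[1]))

    try:
        cadrads = _extract_cadrads(text)
    except _Ambiguous:
        return fail("ambiguous_phrasing")
    if cadrads is None:
        low = text.lower()
        if any(s in low for s in _STENOSIS_SYNONYMS):
            # stenosis described only in synonym vocabulary, no CAD-RADS token
            return fail("ambiguous_phrasing")
        return fail("missing_cadrads")
    spans.append(("cadrads", cadrads[1]))

    flags, anat_spans = _extract_anatomy(text, locale)
    spans.extend(anat_spans)

    try:
        lvef, edv, esv, fn_spans = _extract_function(text, locale)
    except _Malformed:
        return fail("malformed_number")
    if lvef is None:
        return fail("missing_function")
    spans.extend(fn_spans)

    extracoronary = extract_extracoronary(text, locale)

    metrics = KeyMetrics(
        cac_au=cac[0],
        cadrads=cadrads[0],
        lvef_percent=lvef,
        vessel_over50=flags.vessel_over50,
        proximal_lad_over70=flags.proximal_lad_over70,
        soft_plaque_rca_cx_only=flags.soft_plaque_rca_cx_only,
        hrp_present=flags.hrp_present,
        edv_ml=edv,
        esv_ml=esv,
        extracoronary_findings=extracoronary,
    )
    return ParseResult(
        outcome="parsed",
        metrics=metrics,
        matched_spans=tuple(spans),
        locale=locale,
    )
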