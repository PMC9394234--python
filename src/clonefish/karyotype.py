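"""Restricted ISCN karyotype parsing for hyperdiploid gain extraction.

Clinical karyotype strings such as ``"55,XXY,+4,+6,+10,+14,+18,+21,+21/46,XY"``
are reduced to a per-panel-chromosome gain vector so the cytogenetic major
clone can be compared with the major subclone seen by single-cell FISH.

Only the dialect appearing in HHD-B-ALL reports is handled: a modal count
(possibly a range), a sex-chromosome block (possibly with extra X/Y copies
or interleaved ``+X`` tokens), whole-chromosome gain tokens (``+N``, with
optional ``?`` qualifiers), structural tokens (add/del/dup/inv/ins/der/t/mar,
ignored for gain counting), and ``/``-separated clones with ``[n]`` cell
counts.  Full ISCN is a non-goal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .core import DEFAULT_PANEL, ChromosomePanel, SubcloneCode

__all__ = ["KaryotypeGains", "parse_karyotype", "karyotype_concordance"]


@dataclass(frozen=True)
class KaryotypeGains:
    """Panel gains extracted from a karyotype, or an uninformative marker.

    Uninformative covers normal-only karyotypes ("46,XX[20]") and reports
    carrying no countable clone ("High hyperdiploid by FISH").
    """

    gains: Optional[Tuple[int, ...]]

    @property
    def informative(self) -> bool:
        return self.gains is not None

    def as_code(self) -> SubcloneCode:
        if self.gains is None:
            raise ValueError("uninformative karyotype has no gain vector")
        return SubcloneCode(self.gains)


_HYPHENS = "‐‑‒–—−"
_GAIN_TOKEN = re.compile(r"^\+\??([0-9]{1,2}|X|Y)\??$")
_SEX_BLOCK = re.compile(r"^[XY]+$")
_MODAL = re.compile(r"^([0-9]{2,3})(?:\s*[-~]\s*[0-9]{2,3})?$")


def _normalise(text: str) -> str:
    for h in _HYPHENS:
        text = text.replace(h, "-")
    return text.strip()


def _strip_brackets(clone: str) -> str:
    """Drop clone-size annotations like ``[15]``, ``[cp7]`` or ``[56%]``."""
    return re.sub(r"\[[^\]]*\]", "", clone)


def _tokenize(clone: str) -> List[str]:
    toks: List[str] = []
    for raw in _strip_brackets(clone).split(","):
        for tok in raw.split():
            tok = tok.strip()
            if tok:
                toks.append(tok)
    return toks


def _is_normal_clone(tokens: Sequence[str]) -> bool:
    """A clone is constitutionally normal iff it is ``46,XX`` / ``46,XY``."""
    if not tokens:
        return True
    m = _MODAL.match(tokens[0])
    if not m or m.group(1) != "46":
        return False
    rest = [t for t in tokens[1:]]
    return len(rest) == 1 and _SEX_BLOCK.match(rest[0]) is not None


def parse_karyotype(
    iscn: str,
    sex: Optional[str] = None,
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> KaryotypeGains:
    """Extract panel-chromosome gains from the first abnormal clone.

    ``+N`` and ``?``-qualified variants (``+N?``, ``+?N``) each add one gain
    to chromosome N.  The X gain is the surplus of X copies in the
    sex-chromosome block over the constitutional count, plus any ``+X``
    tokens.  Structural tokens and marker chromosomes are ignored.

    Raises ``ValueError`` when the modal/sex block cannot be parsed or when
    the constitutional sex can be determined neither from ``sex`` nor from
    the karyotype itself.
    """
    text = _normalise(iscn)
    if not text:
        raise ValueError("empty karyotype string")

    clones = [c.strip() for c in text.split("/") if c.strip()]
    clone_tokens = [_tokenize(c) for c in clones]

    abnormal = None
    for toks in clone_tokens:
        low = " ".join(toks).lower()
        if "high hyperdiploid" in low or "fish" in low:
            continue
        if not _is_normal_clone(toks):
            abnormal = toks
            break
    if abnormal is None:
        return KaryotypeGains(None)

    m = _MODAL.match(abnormal[0])
    if m is None:
        raise ValueError(f"unparseable modal-number token {abnormal[0]!r} in {iscn!r}")
    body = abnormal[1:]

    # Sex-chromosome block: bare X/Y runs near the front, possibly interleaved
    # with +X / +Y tokens ("54,X,+X,Y,...").
    bare_sex = ""
    i = 0
    while i < len(body):
        tok = body[i]
        if _SEX_BLOCK.match(tok):
            bare_sex += tok
            i += 1
        elif _GAIN_TOKEN.match(tok) and _GAIN_TOKEN.match(tok).group(1) in ("X", "Y"):
            i += 1  # counted below with the other gain tokens
        elif tok in ("-Y", "-X"):
            i += 1
        else:
            break

    if sex is None:
        if bare_sex:
            sex = "M" if "Y" in bare_sex else "F"
        else:
            raise ValueError(
                f"cannot determine constitutional sex for {iscn!r}: no sex given "
                "and no sex-chromosome block found"
            )
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")

    gains = {label: 0 for label in panel.labels}
    constitutional_x = 1 if sex == "M" else 2
    x_in_block = bare_sex.count("X")
    if x_in_block:
        gains["X"] = max(0, x_in_block - constitutional_x)

    for tok in body:
        mt = _GAIN_TOKEN.match(tok)
        if mt is None:
            continue  # structural / marker / non-gain token
        target = mt.group(1)
        if target in gains:
            gains[target] += 1

    return KaryotypeGains(tuple(gains[label] for label in panel.labels))


def karyotype_concordance(
    records: pd.DataFrame,
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> Tuple[pd.DataFrame, int]:
    """Compare karyotype-derived gains with seq-iFISH major clones.

    ``records`` needs columns ``case``, ``karyotype``, ``sex`` and
    ``major_clone`` (8-digit code string).  A case matches iff its karyotype
    is informative and its gain vector equals the major subclone code on all
    panel chromosomes; missing or uninformative karyotypes are non-matches.

    Returns the per-case table (with ``karyotype_code`` and ``match``
    columns) and the total match count.
    """
    rows = []
    for rec in records.itertuples(index=False):
        kt = getattr(rec, "karyotype", None)
        code = SubcloneCode.from_string(str(rec.major_clone))
        if kt is None or (isinstance(kt, float)) or not str(kt).strip():
            rows.append((rec.case, None, str(code), False, "missing karyotype"))
            continue
        parsed = parse_karyotype(str(kt), sex=getattr(rec, "sex", None), panel=panel)
        if not parsed.informative:
            rows.append((rec.case, None, str(code), False, "uninformative karyotype"))
            continue
        kcode = parsed.as_code()
        match = kcode.gains == code.gains
        rows.append((rec.case, str(kcode), str(code), match, ""))
    out = pd.DataFrame(
        rows, columns=["case", "karyotype_code", "major_clone", "match", "note"]
    )
    return out, int(out["match"].sum())
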