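"""In-silico PCR: predict dye-labelled amplicons of a labelled-primer panel.

Exact-match priming only: the assay's primers were validated on conspecific
strains, so a mismatch model would add parameters without adding realism.
Product length follows the standard PCR convention — 5' end of the forward
primer through the 5' end of the reverse primer, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .panel import DyeChannel

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    dye: Optional[DyeChannel] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 15:
            raise ValueError(f"primer {self.name}: length must be >= 15")
        if set(seq) - set("ACGT"):
            raise ValueError(f"primer {self.name}: non-ACGT characters")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class Template:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty template sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    fwd_primer: str
    rev_primer: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    size_bp: int
    dye_set: frozenset

    def __post_init__(self) -> None:
        if self.size_bp != self.end - self.start:
            raise ValueError("size_bp must equal end - start")


def _find_all(haystack: str, needle: str) -> List[int]:
    hits, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return hits
        hits.append(idx)
        start = idx + 1


def find_primer_sites(t: Template, p: Primer) -> List[Tuple[int, str]]:
    """All exact priming sites of ``p`` on either strand of ``t``.

    A ``+`` site at position i means the primer matches t[i:i+len] on the
    forward strand (extension rightwards); a ``-`` site means the reverse
    complement of the primer occupies t[i:i+len] (extension leftwards).
    Positions are 0-based starts on the template.
    """
    sites = [(i, "+") for i in _find_all(t.sequence, p.sequence)]
    sites += [(i, "-") for i in _find_all(t.sequence, revcomp(p.sequence))]
    sites.sort()
    return sites


def predict_amplicons(
    t: Template, primers: Sequence[Primer], max_len: int = 1500
) -> List[Amplicon]:
    """Enumerate every convergent primer pair product of size <= max_len.

    Every (forward-site, reverse-site) combination on opposite strands with
    the forward 5' end upstream of the reverse 5' end yields one amplicon;
    tandem-repeat templates can therefore produce ladders of products from a
    single primer pair.  Results are ordered by (start, size).
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    fwd_sites = []  # (pos5prime, primer)
    rev_sites = []
    for p in primers:
        for pos, strand in find_primer_sites(t, p):
            if strand == "+":
                fwd_sites.append((pos, p))
            else:
                # 5' end of a reverse-strand primer is the rightmost base
                rev_sites.append((pos + len(p.sequence) - 1, p))

    out = []
    for fpos, fp in fwd_sites:
        for rpos, rp in rev_sites:
            if rpos <= fpos:
                continue
            size = rpos - fpos + 1
            if size > max_len:
                continue
            dyes = frozenset(d for d in (fp.dye, rp.dye) if d is not None)
            out.append(
                Amplicon(
                    template_id=t.id,
                    fwd_primer=fp.name,
                    rev_primer=rp.name,
                    start=fpos,
                    end=rpos + 1,
                    size_bp=size,
                    dye_set=dyes,
                )
            )
    out.sort(key=lambda a: (a.start, a.size_bp, a.fwd_primer, a.rev_primer))
    return out


def panel_primers(panel) -> List[Primer]:
    """Primer objects from an :class:`~ssu1_checkup.panel.AllelePanel`."""
    return [
        Primer(name=name, sequence=seq, dye=dye)
        for name, (seq, dye) in sorted(panel.primers.items())
    ]
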