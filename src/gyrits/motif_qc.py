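"""Motif-anchored quality control and ITS1/5.8S/ITS2 partitioning.

Gyrodactylid ITS rDNA submissions are bounded by short, highly conserved
motifs: the 3' end of the 18S gene (``ATCATTA``), the two ends of the
5.8S gene (``CAACTC`` ... ``GTCGGCT``), and the 5' end of the 28S gene
(``CCTGACC``).  The 5.8S gene is invariably 157 bp long in this group.
This module locates those motifs with single-substitution tolerance,
excises the 18S/28S flanks, partitions the remainder into ITS1, 5.8S and
ITS2, raises quality flags for motif variants, indels in the 5.8S and
truncated submissions, and renders the one-line "hologenotype" diagnosis
string used to summarize a reference sequence.

All coordinates in reports are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical boundary motifs
CANONICAL_MOTIFS = {
    "M18S": "ATCATTA",     # 3' end of 18S, ends the upstream flank
    "M58S_5p": "CAACTC",   # first 6 nt of 5.8S
    "M58S_3p": "GTCGGCT",  # last 7 nt of 5.8S
    "M28S": "CCTGACC",     # 5' start of 28S, begins the downstream flank
}

#: the invariant 5.8S gene length in Gyrodactylidae
FIVE_EIGHT_S_LENGTH = 157

#: default end-window for flank motif search (nt)
DEFAULT_WINDOW = 120

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def classify_mismatch(a: str, b: str) -> str:
    """Classify an ordered base pair as identity, transition or transversion."""
    a, b = a.upper(), b.upper()
    if a not in "ACGT" or b not in "ACGT":
        raise ValueError(f"ambiguity codes not classifiable: {a!r} vs {b!r}")
    if a == b:
        return "identity"
    if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class MotifSpec:
    name: str
    canonical: str
    max_mismatches: int = 1
    search_end: str = "interior"   # head | tail | interior

    def __post_init__(self):
        if len(self.canonical) not in (6, 7):
            raise ValueError("canonical motif must be 6 or 7 nt")
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if self.search_end not in ("head", "tail", "interior"):
            raise ValueError(f"bad search_end {self.search_end!r}")


DEFAULT_SPECS = {
    "M18S": MotifSpec("M18S", CANONICAL_MOTIFS["M18S"], search_end="head"),
    "M58S_5p": MotifSpec("M58S_5p", CANONICAL_MOTIFS["M58S_5p"]),
    "M58S_3p": MotifSpec("M58S_3p", CANONICAL_MOTIFS["M58S_3p"]),
    "M28S": MotifSpec("M28S", CANONICAL_MOTIFS["M28S"], search_end="tail"),
}


@dataclass(frozen=True)
class MotifHit:
    spec: MotifSpec
    start: int              # 1-based on the searched sequence
    observed: str
    mismatches: tuple       # of (pos_in_motif 1-based, canonical, observed, class)
    ambiguous_match: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.spec.canonical) - 1

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def _score_at(seq: str, pos0: int, spec: MotifSpec):
    """Mismatch list for the motif laid at 0-based pos0, or None if out of range."""
    k = len(spec.canonical)
    window = seq[pos0:pos0 + k]
    if len(window) < k:
        return None
    mismatches, ambiguous = [], False
    for i, (canon, obs) in enumerate(zip(spec.canonical, window)):
        obs_set = IUPAC.get(obs.upper())
        if obs_set is None:
            mismatches.append((i + 1, canon, obs, "invalid"))
        elif obs.upper() == canon:
            continue
        elif canon in obs_set:
            # ambiguity code covering the canonical base: match with warning
            ambiguous = True
        elif obs.upper() in "ACGT":
            mismatches.append((i + 1, canon, obs.upper(),
                               classify_mismatch(canon, obs)))
        else:
            mismatches.append((i + 1, canon, obs.upper(), "ambiguous"))
    return mismatches, ambiguous


def _search_range(seq_len: int, spec: MotifSpec, window: int):
    if spec.search_end == "head":
        return 0, min(window, seq_len)
    if spec.search_end == "tail":
        return max(0, seq_len - window), seq_len
    return 0, seq_len


def find_all_motif_hits(seq: str, spec: MotifSpec, window: int = DEFAULT_WINDOW):
    """Every placement with mismatch count within tolerance, left to right."""
    lo, hi = _search_range(len(seq), spec, window)
    hits = []
    for pos0 in range(lo, hi - len(spec.canonical) + 1):
        scored = _score_at(seq, pos0, spec)
        if scored is None:
            continue
        mism, amb = scored
        if len(mism) <= spec.max_mismatches:
            hits.append(MotifHit(spec, pos0 + 1,
                                 seq[pos0:pos0 + len(spec.canonical)].upper(),
                                 tuple(mism), amb))
    return hits


def find_motif(seq: str, spec: MotifSpec, window: int = DEFAULT_WINDOW):
    """Best motif placement, or None.

    The hit with fewest mismatches wins.  Ties are broken by proximity
    to the sequence end the motif bounds: rightmost for head searches
    (the motif ends the upstream flank), leftmost for tail and interior
    searches.
    """
    hits = find_all_motif_hits(seq, spec, window)
    if not hits:
        return None
    if spec.search_end == "head":
        return min(hits, key=lambda h: (h.n_mismatches, -h.start))
    return min(hits, key=lambda h: (h.n_mismatches, h.start))


# ---------------------------------------------------------------------------
# region annotation


@dataclass
class Region:
    name: str
    start: int | None       # 1-based inclusive on the original sequence
    end: int | None
    complete: bool = False
    sequence: str = ""

    @property
    def length(self):
        return len(self.sequence) if self.sequence else None

    @property
    def first7(self):
        return self.sequence[:7] if self.sequence else ""

    @property
    def last7(self):
        return self.sequence[-7:] if self.sequence else ""


@dataclass
class RegionAnnotation:
    regions: dict               # name -> Region for ITS1, 5.8S, ITS2
    motif_hits: dict            # name -> MotifHit or None

    @property
    def total_trimmed_length(self):
        lens = [r.length for r in self.regions.values()]
        if any(l is None for l in lens):
            return None
        return sum(lens)

    def region(self, name) -> Region:
        return self.regions[name]


@dataclass
class QCReport:
    flags: set = field(default_factory=set)
    disposition: str = "pass"
    notes: list = field(default_factory=list)


def _variant_flags(hit: MotifHit):
    flags = set()
    for (_pos, _canon, _obs, klass) in hit.mismatches:
        if klass == "transition":
            flags.add(f"motif_variant_transition({hit.spec.name})")
        elif klass == "transversion":
            flags.add(f"motif_variant_transversion({hit.spec.name})")
        else:
            flags.add(f"motif_variant_ambiguous({hit.spec.name})")
    return flags


def annotate_its(seq: str, motif_specs: dict | None = None,
                 windows: dict | None = None):
    """Locate boundary motifs and partition a raw ITS submission.

    Returns ``(RegionAnnotation, QCReport)``.  The 18S/28S flank motifs
    are sought within an end window (default 120 nt); the 5.8S motifs
    are sought over the whole sequence, and among candidate 5'/3' motif
    pairs the pair whose implied 5.8S length is closest to 157 (then
    fewest total mismatches, then leftmost) is chosen.  A missing 18S
    motif leaves ITS1 incomplete, starting at position 1; a missing 28S
    motif leaves ITS2 incomplete, ending at the sequence end.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < 50:
        raise ValueError("sequence shorter than 50 nt")
    seq = seq.upper()
    specs = dict(DEFAULT_SPECS)
    if motif_specs:
        specs.update(motif_specs)
    windows = windows or {}
    w18 = windows.get("M18S", DEFAULT_WINDOW)
    w28 = windows.get("M28S", DEFAULT_WINDOW)

    report = QCReport()
    hit18 = find_motif(seq, specs["M18S"], w18)
    hit28 = find_motif(seq, specs["M28S"], w28)

    hits5p = find_all_motif_hits(seq, specs["M58S_5p"])
    hits3p = find_all_motif_hits(seq, specs["M58S_3p"])
    # restrict 5.8S candidates to the span between the flank motifs
    if hit18:
        hits5p = [h for h in hits5p if h.start > hit18.end]
        hits3p = [h for h in hits3p if h.start > hit18.end]
    if hit28:
        hits5p = [h for h in hits5p if h.end < hit28.start]
        hits3p = [h for h in hits3p if h.end < hit28.start]

    hit5p = hit3p = None
    pairs = [(a, b) for a in hits5p for b in hits3p if b.end > a.start]
    if pairs:
        def pair_key(ab):
            a, b = ab
            implied = b.end - a.start + 1
            return (abs(implied - FIVE_EIGHT_S_LENGTH),
                    a.n_mismatches + b.n_mismatches, a.start)
        hit5p, hit3p = min(pairs, key=pair_key)
    elif hits5p:
        hit5p = min(hits5p, key=lambda h: (h.n_mismatches, h.start))
    elif hits3p:
        hit3p = min(hits3p, key=lambda h: (h.n_mismatches, h.start))

    hits = {"M18S": hit18, "M58S_5p": hit5p, "M58S_3p": hit3p, "M28S": hit28}

    # ---- flags ------------------------------------------------------
    for name, hit in hits.items():
        if hit is None:
            report.flags.add(f"motif_missing({name})")
        else:
            if hit.n_mismatches:
                report.flags |= _variant_flags(hit)
            if hit.ambiguous_match:
                report.notes.append(f"{name}: ambiguity code covers canonical base")
    if hit18 is None:
        report.flags.add("truncated_5p")
        if hit5p or hit3p:
            report.flags.add("aberrant_18S_end")
    elif hit18.n_mismatches:
        report.flags.add("aberrant_18S_end")
    if hit28 is None:
        report.flags.add("truncated_3p")
    elif hit28.n_mismatches:
        observed9 = seq[hit28.start - 1:hit28.start + 8]
        report.flags.add(f"nonstandard_28S_motif({observed9})")

    # ---- regions ----------------------------------------------------
    def mk(name, start, end, complete):
        if start is None or end is None or end < start:
            return Region(name, None, None, False, "")
        return Region(name, start, end, complete, seq[start - 1:end])

    its1_start = hit18.end + 1 if hit18 else 1
    its1_end = hit5p.start - 1 if hit5p else None
    s58_start = hit5p.start if hit5p else None
    s58_end = hit3p.end if hit3p else None
    its2_start = hit3p.end + 1 if hit3p else None
    its2_end = hit28.start - 1 if hit28 else len(seq)

    regions = {
        "ITS1": mk("ITS1", its1_start, its1_end,
                   hit18 is not None and hit5p is not None),
        "5.8S": mk("5.8S", s58_start, s58_end,
                   hit5p is not None and hit3p is not None),
        "ITS2": mk("ITS2", its2_start, its2_end,
                   hit3p is not None and hit28 is not None),
    }
    annotation = RegionAnnotation(regions, hits)

    s58 = regions["5.8S"]
    if s58.complete and s58.length != FIVE_EIGHT_S_LENGTH:
        delta = s58.length - FIVE_EIGHT_S_LENGTH
        report.flags.add(f"fivepointeight_length_deviation({delta:+d})")

    # ---- disposition ------------------------------------------------
    if any(f.startswith("motif_missing") for f in report.flags):
        report.disposition = "review"
    elif report.flags:
        report.disposition = "pass_with_warnings"
    else:
        report.disposition = "pass"
    return annotation, report


def diagnose(annotation: RegionAnnotation, record_id: str) -> str:
    """Render the one-line hologenotype diagnosis string.

    Format: ``ITS rDNA (<id>) <total> bp: ITS1 <complete|incomplete>
    <first7> to <last7> <len> bp, 5.8S ..., ITS2 ...``.  The total is
    the arithmetic sum of the region lengths; an undeterminable region
    renders as "not determined".
    """
    total = annotation.total_trimmed_length
    total_str = f"{total} bp" if total is not None else "length not determined"
    parts = []
    for name in ("ITS1", "5.8S", "ITS2"):
        r = annotation.region(name)
        status = "complete" if r.complete else "incomplete"
        if r.length is None:
            parts.append(f"{name} not determined")
        else:
            parts.append(f"{name} {status} {r.first7} to {r.last7} {r.length} bp")
    return f"ITS rDNA ({record_id}) {total_str}: " + ", ".join(parts)


def parse_diagnosis(text: str) -> dict:
    """Invert :func:`diagnose`: extract region lengths and heptamers."""
    import re
    out = {}
    m = re.search(r"\((\S+)\) (\d+) bp:", text)
    if m:
        out["id"], out["total"] = m.group(1), int(m.group(2))
    for name in ("ITS1", "5.8S", "ITS2"):
        m = re.search(rf"{name} (complete|incomplete) (\S+) to (\S+) (\d+) bp",
                      text)
        if m:
            out[name] = {"status": m.group(1), "first7": m.group(2),
                         "last7": m.group(3), "length": int(m.group(4))}
    return out


def verify_reported_total(annotation: RegionAnnotation, record_id: str,
                          reported_total: int):
    """Check a database/published total against the sum of the parts.

    Returns ``(computed_total, agrees)`` and logs a warning when the
    reported figure differs from the arithmetic sum of the region
    lengths (as happens for some published annotations).
    """
    import logging
    computed = annotation.total_trimmed_length
    agrees = computed == reported_total
    if computed is not None and not agrees:
        logging.getLogger("gyrits").warning(
            "%s: reported total %d bp != sum of parts %d bp",
            record_id, reported_total, computed)
    return computed, agrees


def batch_qc(records, motif_specs=None, windows=None):
    """QC a batch of (id, sequence) pairs.

    Returns ``(table, summary)``: one row per record with region
    lengths, flags and disposition; the summary names the shortest and
    longest trimmed records among pass/pass_with_warnings rows.
    Per-record failures become disposition ``review`` rows and never
    abort the batch.
    """
    records = list(records)
    if not records:
        raise ValueError("empty batch")
    rows = []
    for rec_id, seq in records:
        try:
            ann, rep = annotate_its(seq, motif_specs, windows)
            rows.append({
                "id": rec_id,
                "its1_len": ann.region("ITS1").length,
                "fiveeights_len": ann.region("5.8S").length,
                "its2_len": ann.region("ITS2").length,
                "total": ann.total_trimmed_length,
                "flags": ";".join(sorted(rep.flags)),
                "disposition": rep.disposition,
            })
        except Exception as exc:  # noqa: BLE001 — per-record robustness
            rows.append({"id": rec_id, "its1_len": None, "fiveeights_len": None,
                         "its2_len": None, "total": None,
                         "flags": f"error({exc})", "disposition": "review"})
    table = pd.DataFrame(rows)
    ok = table[table["disposition"].isin(["pass", "pass_with_warnings"])
               & table["total"].notna()]
    summary = {}
    if len(ok):
        shortest = ok.loc[ok["total"].idxmin()]
        longest = ok.loc[ok["total"].idxmax()]
        summary = {"shortest_id": shortest["id"], "shortest_total": int(shortest["total"]),
                   "longest_id": longest["id"], "longest_total": int(longest["total"])}
    return table, summary
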