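"""Synthetic ITS records, sequence pairs and tree alignments with known truth.

Everything downstream of GenBank — motif annotation, distance
estimation, monophyly evaluation — is tested against data produced
here, where the ground truth (region coordinates, injected defects,
true branch lengths, true clades) is known by construction.

Generated ITS records have the layout

    [18S flank ... ATCATTA][ITS1][CAACTC ... GTCGGCT][ITS2][CCTGACC ... 28S flank]

with an exactly 157-nt 5.8S.  Background (non-motif) composition is
i.i.d. from a configurable base-frequency vector (uniform by default);
background windows within one substitution of any canonical boundary
motif are resampled so that the only motif signals in a clean record
are the intended ones.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .distances import Partition, PartitionedAlignment
from .models import BASES, SubstitutionModel, transition_probability
from .motif_qc import (CANONICAL_MOTIFS, DEFAULT_SPECS, FIVE_EIGHT_S_LENGTH,
                       MotifHit, Region, RegionAnnotation)

_MOTIF_LEN = {k: len(v) for k, v in CANONICAL_MOTIFS.items()}

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class ITSTemplate:
    """Layout of a synthetic pre-excision ITS submission."""
    flank18_len: int = 60
    its1_len: int = 343
    its2_len: int = 289
    flank28_len: int = 60
    seed: int = 0
    base_frequencies: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.its1_len < 7 or self.its2_len < 7:
            raise ValueError("ITS regions must be >= 7 nt to carry boundary heptamers")
        if self.flank18_len < 7 or self.flank28_len < 7:
            raise ValueError("flanks must be at least as long as their motif")
        pi = np.asarray(self.base_frequencies)
        if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
            raise ValueError("base frequencies must be a probability vector")


def _random_background(rng: np.random.Generator, length: int, pi) -> str:
    """i.i.d. background with motif-like windows resampled away."""
    if length == 0:
        return ""
    seq = list(rng.choice(list(BASES), size=length, p=pi))
    changed = True
    guard = 0
    while changed and guard < 100:
        changed = False
        guard += 1
        s = "".join(seq)
        for motif in CANONICAL_MOTIFS.values():
            k = len(motif)
            for pos in range(0, length - k + 1):
                if sum(a != b for a, b in zip(s[pos:pos + k], motif)) <= 1:
                    for j in range(pos, pos + k):
                        seq[j] = rng.choice(list(BASES), p=pi)
                    changed = True
                    s = "".join(seq)
    return "".join(seq)


def _spurious_near_motifs(seq: str, true_starts0: dict) -> bool:
    """Any window within one substitution of a motif away from its true site?

    ``true_starts0`` maps motif name -> 0-based start of the genuine
    occurrence.  Junction windows spanning two generated segments are
    not covered by the per-segment scrub, so the assembled record is
    re-scanned as a whole.
    """
    for name, motif in CANONICAL_MOTIFS.items():
        k = len(motif)
        for pos in range(0, len(seq) - k + 1):
            if pos == true_starts0[name]:
                continue
            if sum(a != b for a, b in zip(seq[pos:pos + k], motif)) <= 1:
                return True
    return False


def make_reference_its(template: ITSTemplate):
    """Build a clean pre-excision ITS record and its exact truth annotation.

    Returns ``(sequence, truth)`` where ``truth`` is a
    :class:`~gyrits.motif_qc.RegionAnnotation` giving the 1-based motif
    and region coordinates the annotator must recover.
    """
    rng = np.random.default_rng(template.seed)
    pi = np.asarray(template.base_frequencies, dtype=float)
    pi = pi / pi.sum()

    m18, m5p, m3p, m28 = (CANONICAL_MOTIFS[k]
                          for k in ("M18S", "M58S_5p", "M58S_3p", "M28S"))
    f18 = template.flank18_len
    its1_start = f18 + 1
    s58_start = f18 + template.its1_len + 1
    its2_start = s58_start + FIVE_EIGHT_S_LENGTH
    m28_start = its2_start + template.its2_len
    true_starts0 = {"M18S": f18 - len(m18), "M58S_5p": s58_start - 1,
                    "M58S_3p": its2_start - 1 - len(m3p),
                    "M28S": m28_start - 1}

    for _attempt in range(50):
        flank18 = _random_background(rng, template.flank18_len - len(m18), pi) + m18
        its1 = _random_background(rng, template.its1_len, pi)
        core58 = (m5p
                  + _random_background(
                      rng, FIVE_EIGHT_S_LENGTH - len(m5p) - len(m3p), pi)
                  + m3p)
        its2 = _random_background(rng, template.its2_len, pi)
        flank28 = m28 + _random_background(rng, template.flank28_len - len(m28), pi)
        seq = flank18 + its1 + core58 + its2 + flank28
        if not _spurious_near_motifs(seq, true_starts0):
            break
    else:  # pragma: no cover — vanishingly unlikely
        raise RuntimeError("could not assemble a motif-clean record")

    def hit(name, start):
        spec = DEFAULT_SPECS[name]
        return MotifHit(spec, start, seq[start - 1:start - 1 + len(spec.canonical)],
                        ())

    hits = {
        "M18S": hit("M18S", f18 - len(m18) + 1),
        "M58S_5p": hit("M58S_5p", s58_start),
        "M58S_3p": hit("M58S_3p", its2_start - len(m3p)),
        "M28S": hit("M28S", m28_start),
    }
    regions = {
        "ITS1": Region("ITS1", its1_start, s58_start - 1, True, its1),
        "5.8S": Region("5.8S", s58_start, its2_start - 1, True, core58),
        "ITS2": Region("ITS2", its2_start, m28_start - 1, True, its2),
    }
    return seq, RegionAnnotation(regions, hits)


# ---------------------------------------------------------------------------
# mutation injection


@dataclass(frozen=True)
class MutationSpec:
    """A single targeted defect relative to a clean reference record.

    ``transition``/``transversion`` substitute one base at
    ``position_in_motif`` (1-based within the motif).  ``insertion`` and
    ``deletion`` act in the region interior immediately adjacent to the
    motif (downstream of 5'-side motifs, upstream of 3'-side motifs),
    shifting the region length by +/- ``count`` without touching the
    motif itself.  ``truncate_5p``/``truncate_3p`` remove the motif and
    ``count`` additional interior bases, emulating submissions whose
    flanks were clipped before deposit.
    """
    target_motif: str
    position_in_motif: int = 1
    kind: str = "transition"
    count: int = 1

    def __post_init__(self):
        if self.target_motif not in CANONICAL_MOTIFS:
            raise ValueError(f"unknown motif {self.target_motif!r}")
        kinds = ("transition", "transversion", "insertion", "deletion",
                 "truncate_5p", "truncate_3p")
        if self.kind not in kinds:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not (1 <= self.position_in_motif <= _MOTIF_LEN[self.target_motif]):
            raise ValueError("position_in_motif out of range")

    @property
    def destructive(self) -> bool:
        return self.kind in ("insertion", "deletion", "truncate_5p", "truncate_3p")


def _check_spec_compatibility(specs):
    for a, b in itertools.combinations(specs, 2):
        if a.target_motif != b.target_motif:
            continue
        if a.destructive or b.destructive:
            raise ValueError(
                f"overlapping destructive specs on motif {a.target_motif}")
        if a.position_in_motif == b.position_in_motif:
            raise ValueError(
                f"two substitutions at the same position of {a.target_motif}")


def _scrub_unintended_near_motifs(seq: list, spans: dict, rng,
                                  max_rounds: int = 100):
    """Remove chance windows within 1 substitution of any canonical motif.

    ``spans`` maps motif name -> (0-based start, length) of the genuine
    (possibly variant-carrying) occurrence, which is left untouched;
    offending windows are fixed by bumping one background base (any
    position outside all genuine spans) to a non-canonical value.
    """
    protected = set()
    for start0, length in spans.values():
        protected.update(range(start0, start0 + length))
    for _ in range(max_rounds):
        dirty = False
        s = "".join(seq)
        for name, motif in CANONICAL_MOTIFS.items():
            k = len(motif)
            true_start = spans.get(name, (-1, 0))[0]
            for pos in range(0, len(s) - k + 1):
                if pos == true_start:
                    continue
                if sum(a != b for a, b in zip(s[pos:pos + k], motif)) > 1:
                    continue
                editable = [i for i in range(pos, pos + k)
                            if i not in protected]
                if not editable:
                    continue
                # prefer a position currently matching the canonical base,
                # so the change is guaranteed to add a mismatch
                matching = [i for i in editable if seq[i] == motif[i - pos]]
                idx = (matching or editable)[0]
                choices = [b for b in BASES
                           if b != motif[idx - pos] and b != seq[idx]]
                seq[idx] = rng.choice(choices)
                dirty = True
                s = "".join(seq)
        if not dirty:
            return


def apply_mutations(record: str, truth: RegionAnnotation, specs, seed: int = 0):
    """Inject defects into a clean record.

    Returns ``(mutated, expected_flags, expected_lengths)``:
    ``expected_flags`` is the set of QC flags
    :func:`~gyrits.motif_qc.annotate_its` must raise on the mutated
    record (empty for an empty spec list); ``expected_lengths`` maps
    region name to the length the annotator should report (``None``
    where a destroyed boundary makes the region undeterminable).
    """
    specs = list(specs)
    _check_spec_compatibility(specs)
    rng = np.random.default_rng(seed)
    seq = list(record)
    expected = set()

    # per-motif substitution bookkeeping for >=2-change destruction
    sub_counts = {}

    # apply in descending sequence position so indices stay valid
    def motif_hit(name):
        return truth.motif_hits[name]

    edits = []  # (position0, op, payload)
    for spec in specs:
        hit = motif_hit(spec.target_motif)
        if spec.kind in ("transition", "transversion"):
            pos0 = hit.start - 1 + spec.position_in_motif - 1
            base = record[pos0]
            if spec.kind == "transition":
                new = _TRANSITION_PARTNER[base]
            else:
                new = rng.choice(list(_TRANSVERSIONS[base]))
            edits.append((pos0, "sub", new))
            sub_counts.setdefault(spec.target_motif, []).append(spec.kind)
        elif spec.kind == "insertion":
            if spec.target_motif in ("M18S", "M58S_5p"):
                pos0 = hit.end  # insert right after the motif
            else:
                pos0 = hit.start - 1  # insert right before the motif
            ins = "".join(rng.choice(list(BASES), size=spec.count))
            edits.append((pos0, "ins", ins))
            if spec.target_motif in ("M58S_5p", "M58S_3p"):
                expected.add(f"fivepointeight_length_deviation({spec.count:+d})")
        elif spec.kind == "deletion":
            if spec.target_motif in ("M18S", "M58S_5p"):
                pos0 = hit.end
            else:
                pos0 = hit.start - 1 - spec.count
            edits.append((pos0, "del", spec.count))
            if spec.target_motif in ("M58S_5p", "M58S_3p"):
                expected.add(f"fivepointeight_length_deviation({-spec.count:+d})")
        elif spec.kind == "truncate_5p":
            if spec.target_motif != "M18S":
                raise ValueError("truncate_5p applies to M18S")
            edits.append((0, "cut_head", hit.end + spec.count))
            expected |= {"motif_missing(M18S)", "truncated_5p",
                         "aberrant_18S_end"}
        elif spec.kind == "truncate_3p":
            if spec.target_motif != "M28S":
                raise ValueError("truncate_3p applies to M28S")
            edits.append((0, "cut_tail", len(record) - hit.start + 1 + spec.count))
            expected |= {"motif_missing(M28S)", "truncated_3p"}

    # expected region lengths after the edits
    lengths = {"ITS1": truth.region("ITS1").length,
               "5.8S": truth.region("5.8S").length,
               "ITS2": truth.region("ITS2").length}
    _REGION_OF = {"M18S": "ITS1", "M58S_5p": "5.8S",
                  "M58S_3p": "5.8S", "M28S": "ITS2"}
    for spec in specs:
        region = _REGION_OF[spec.target_motif]
        if spec.kind == "insertion":
            lengths[region] += spec.count
        elif spec.kind == "deletion":
            lengths[region] -= spec.count
        elif spec.kind == "truncate_5p":
            lengths["ITS1"] -= spec.count
        elif spec.kind == "truncate_3p":
            lengths["ITS2"] -= spec.count
    for motif, kinds in sub_counts.items():
        if len(kinds) < 2:
            continue
        # >=2 substitutions destroy the motif: without the anchor the
        # annotator absorbs an intact flank into the spacer, or loses
        # the regions the anchor bounded
        if motif == "M18S":
            lengths["ITS1"] += truth.motif_hits["M18S"].end
        elif motif == "M28S":
            lengths["ITS2"] += len(record) - truth.motif_hits["M28S"].start + 1
        elif motif == "M58S_5p":
            lengths["ITS1"] = None
            lengths["5.8S"] = None
        elif motif == "M58S_3p":
            lengths["5.8S"] = None
            lengths["ITS2"] = None

    # expected flags for substitutions
    for motif, kinds in sub_counts.items():
        if len(kinds) >= 2:
            expected.add(f"motif_missing({motif})")
            if motif == "M18S":
                expected |= {"aberrant_18S_end", "truncated_5p"}
            if motif == "M28S":
                expected.add("truncated_3p")
        else:
            expected.add(f"motif_variant_{kinds[0]}({motif})")
            if motif == "M18S":
                expected.add("aberrant_18S_end")

    for pos0, op, payload in sorted(edits, key=lambda e: -e[0]):
        if op == "sub":
            seq[pos0] = payload
        elif op == "ins":
            seq[pos0:pos0] = list(payload)
        elif op == "del":
            del seq[pos0:pos0 + payload]
        elif op == "cut_head":
            del seq[:payload]
        elif op == "cut_tail":
            del seq[len(seq) - payload:]

    # the edits themselves can create chance near-motif windows (e.g. a
    # destroyed motif re-matching one position over with help from the
    # background); rescrub background bases so the only motif signals are
    # the intended ones
    removed = {s.target_motif for s in specs
               if s.kind in ("truncate_5p", "truncate_3p")}
    spans = {}
    for name, hit in truth.motif_hits.items():
        if name in removed:
            continue
        start0 = hit.start - 1
        shift = 0
        for pos0, op, payload in edits:
            if op == "ins" and pos0 <= start0:
                shift += len(payload)
            elif op == "del" and pos0 + payload <= start0:
                shift -= payload
            elif op == "cut_head":
                shift -= payload
        spans[name] = (start0 + shift, len(hit.spec.canonical))
    _scrub_unintended_near_motifs(seq, spans, rng)

    mutated = "".join(seq)
    # a mutated M28S with one substitution is reported with its observed
    # 9-mer; every length-changing edit lies upstream of the motif, so the
    # net length shift relocates it exactly
    if "M28S" in sub_counts and len(sub_counts["M28S"]) == 1:
        start0 = motif_hit("M28S").start - 1 + (len(mutated) - len(record))
        expected.add(f"nonstandard_28S_motif({mutated[start0:start0 + 9]})")
    return mutated, expected, lengths


# ---------------------------------------------------------------------------
# pair and tree simulation


@dataclass(frozen=True)
class SimulatedPair:
    seq_a: str
    seq_b: str
    true_distance: float
    model: SubstitutionModel
    seed: int


def _draw_children(rng, ancestors, t, model):
    """Evolve integer-coded sites for time t with per-site gamma categories."""
    rates = model.rates()
    cats = rng.integers(0, len(rates), size=ancestors.size)
    children = np.empty_like(ancestors)
    for c, r in enumerate(rates):
        idx = np.flatnonzero(cats == c)
        if idx.size == 0:
            continue
        P = transition_probability(model, t, r)
        u = rng.random(idx.size)
        cum = np.cumsum(P[ancestors[idx]], axis=1)
        children[idx] = (u[:, None] > cum).sum(axis=1)
    return children


def simulate_pair(model: SubstitutionModel, t: float, n_sites: int,
                  seed: int = 0) -> SimulatedPair:
    """Two sequences separated by branch length t (substitutions/site).

    Sites are i.i.d.: the ancestral base is drawn from the stationary
    frequencies, each site's rate is drawn uniformly from the discrete
    gamma categories, and the descendant base from exp(Q t r).  The
    simulation is substitution-only (no gaps).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    rng = np.random.default_rng(seed)
    anc = rng.choice(4, size=n_sites, p=model.pi)
    if t == 0:
        child = anc.copy()
    else:
        child = _draw_children(rng, anc, t, model)
    to_str = lambda arr: "".join(BASES[i] for i in arr)
    return SimulatedPair(to_str(anc), to_str(child), t, model, seed)


def simulate_alignment_on_tree(tree, partitions, seed: int = 0):
    """Evolve a gap-free partitioned alignment along a tree.

    ``tree`` is a Newick string or a :class:`dendropy.Tree` with branch
    lengths; ``partitions`` is a list of ``(name, length, model)``.
    Per-site rate categories are drawn once per partition and shared
    across the whole tree (rates are site properties).  Returns
    ``(PartitionedAlignment, tree)``.
    """
    import dendropy
    if isinstance(tree, str):
        try:
            tree = dendropy.Tree.get(data=tree, schema="newick",
                                     preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate tip names: {exc}") from exc
    labels = [lf.taxon.label if lf.taxon else None
              for lf in tree.leaf_node_iter()]
    if any(l is None for l in labels):
        raise ValueError("all tips must be named")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip names")

    rng = np.random.default_rng(seed)
    tip_seqs = {l: [] for l in labels}
    for name, length, model in partitions:
        if length <= 0:
            raise ValueError(f"partition {name} has non-positive length")
        rates = model.rates()
        cats = rng.integers(0, len(rates), size=length)
        root_states = rng.choice(4, size=length, p=model.pi)
        node_states = {tree.seed_node: root_states}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            bl = node.edge.length
            if bl is None:
                raise ValueError("tree must have branch lengths on every edge")
            parent_states = node_states[node.parent_node]
            if bl == 0:
                states = parent_states.copy()
            else:
                states = np.empty(length, dtype=parent_states.dtype)
                for c, r in enumerate(rates):
                    idx = np.flatnonzero(cats == c)
                    if idx.size == 0:
                        continue
                    P = transition_probability(model, bl, r)
                    u = rng.random(idx.size)
                    cum = np.cumsum(P[parent_states[idx]], axis=1)
                    states[idx] = (u[:, None] > cum).sum(axis=1)
            node_states[node] = states
        for lf in tree.leaf_node_iter():
            tip_seqs[lf.taxon.label].append(
                "".join(BASES[i] for i in node_states[lf]))

    rows = ["".join(parts) for parts in
            (tip_seqs[l] for l in labels)]
    offsets = np.cumsum([0] + [length for _, length, _ in partitions])
    parts = [Partition(name, int(offsets[i]) + 1, int(offsets[i + 1]), model)
             for i, (name, length, model) in enumerate(partitions)]
    aln = PartitionedAlignment(list(labels), rows, parts)
    return aln, tree


def standard_mutation_scenarios():
    """Named defect scenarios spanning the QC flag vocabulary.

    Used to exercise the annotator against generated records with known
    expected flags and region lengths.
    """
    return [
        ("clean", []),
        ("m58s5p_transition_caactt", [MutationSpec("M58S_5p", 6, "transition")]),
        ("m58s3p_transversion", [MutationSpec("M58S_3p", 7, "transversion")]),
        ("m18s_transition", [MutationSpec("M18S", 5, "transition")]),
        ("m28s_transition", [MutationSpec("M28S", 1, "transition")]),
        ("fiveeights_insertion", [MutationSpec("M58S_5p", 1, "insertion")]),
        ("fiveeights_double_insertion",
         [MutationSpec("M58S_5p", 1, "insertion", count=2)]),
        ("fiveeights_deletion", [MutationSpec("M58S_3p", 1, "deletion")]),
        ("head_truncated", [MutationSpec("M18S", 1, "truncate_5p", count=10)]),
        ("tail_truncated", [MutationSpec("M28S", 1, "truncate_3p", count=5)]),
        ("m18s_destroyed", [MutationSpec("M18S", 2, "transition"),
                            MutationSpec("M18S", 5, "transversion")]),
        ("m58s5p_destroyed", [MutationSpec("M58S_5p", 2, "transition"),
                              MutationSpec("M58S_5p", 5, "transversion")]),
    ]


def truth_table(records):
    """TSV-ready truth rows for (record_id, truth, expected_flags) triples."""
    import pandas as pd
    rows = []
    for rec_id, truth, flags in records:
        for name in ("ITS1", "5.8S", "ITS2"):
            r = truth.region(name)
            rows.append({"record_id": rec_id, "region": name,
                         "start": r.start, "end": r.end, "length": r.length,
                         "expected_flags": ";".join(sorted(flags))})
    return pd.DataFrame(rows)
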