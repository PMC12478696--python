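"""Attention-head interpretability: from attention weights back to motifs.

Pipeline (run on positive test samples of a trained model):

1. capture the per-head attention maps (heads x 246 x 246 under defaults;
   rows 0..147 are enhancer regions, 148..245 promoter regions);
2. map any merged region index back to its receptive field on the raw
   sequence (59 bp under the default 40/20/20 geometry);
3. re-run the convolution/pooling stages on the sequences and, per region,
   extract the kernel-width window with the strongest activation from each
   sample; aggregate base counts into a position weight matrix (PWM);
4. rank enhancer-region x promoter-region pairs by their averaged
   cross-block attention scores (the top 5-8 by default);
5. export PWMs in minimal MEME motif format for motif-comparison tools,
   read back TOMTOM result TSVs (thresholds e-value < 0.07, p < 1e-4) and a
   BioGRID TAB export, and join them into a table of TF(enhancer) x
   TF(promoter) interactions with cell-line support and evidence types.

No external tool is ever invoked; only the interchange formats are
produced and consumed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .records import SequencePairRecord
from .encodings import seq_to_indices, embed_onehot

logger = logging.getLogger(__name__)

BASES = "ACGT"


class InterpretError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Region geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionWindow:
    """Receptive field of one merged region on its raw sequence.

    ``r`` is the merged index; enhancer regions come first.  ``start``/
    ``end`` are 0-based half-open coordinates on the enhancer or promoter
    sequence according to ``role``.
    """

    r: int
    role: str          # {"enhancer", "promoter"}
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.role}_region_{self.r}"


def region_window(r: int, cfg: ModelConfig) -> RegionWindow:
    """Receptive field of merged region r: the union of the conv windows
    covered by pool window r, clipped to the sequence length.

    Under default geometry (kernel 40, pool 20/20) this is
    [20r, 20r + 59) on the enhancer for r < 148 and
    [20(r-148), 20(r-148) + 59) on the promoter for r >= 148.
    """
    L_enh = cfg.enh_pooled_len
    L_all = cfg.merged_len
    if not 0 <= r < L_all:
        raise InterpretError(f"region index {r} out of range [0, {L_all})")
    if r < L_enh:
        role, local, seq_len = "enhancer", r, cfg.enh_len
    else:
        role, local, seq_len = "promoter", r - L_enh, cfg.prom_len
    start = local * cfg.pool_stride
    end = start + cfg.pool_size - 1 + cfg.conv_kernel
    if cfg.encoding == "dna2vec":
        end += cfg.kmer_k - 1   # each token spans k bases
    return RegionWindow(r, role, start, min(end, seq_len))


# ---------------------------------------------------------------------------
# Attention capture and averaging
# ---------------------------------------------------------------------------

def capture_attention(model_or_results, records: list[SequencePairRecord],
                      batch_size: int = 64) -> np.ndarray:
    """Per-sample, per-head attention maps for positive records.

    Returns an array (n_samples, n_heads, L_merged, L_merged); every row of
    every head is a softmax distribution.  Raises if no records are given or
    any record is negative (the extraction protocol is defined on positive
    test samples).
    """
    net = getattr(model_or_results, "network", model_or_results)
    if not records:
        raise InterpretError("attention capture needs at least one positive record")
    bad = [r.id for r in records if r.label != 1]
    if bad:
        raise InterpretError(f"attention capture requires positive records; negatives: {bad[:5]}")
    maps = []
    for lo in range(0, len(records), batch_size):
        chunk = records[lo:lo + batch_size]
        xe = net.encode_batch([r.enhancer for r in chunk], "enhancer")
        xp = net.encode_batch([r.promoter for r in chunk], "promoter")
        _, attn = net.forward(xe, xp, training=False, capture_attention=True)
        maps.append(attn)
    return np.concatenate(maps, axis=0)


def average_heads(maps: np.ndarray) -> np.ndarray:
    """Elementwise mean over heads (and samples, if present): (..., L, L) -> (L, L).

    The query->key direction is preserved; no symmetrization.
    """
    maps = np.asarray(maps)
    if maps.size == 0:
        raise InterpretError("cannot average an empty attention stack")
    if maps.ndim < 2:
        raise InterpretError("expected at least a 2-D attention matrix")
    while maps.ndim > 2:
        maps = maps.mean(axis=0)
    return maps


# ---------------------------------------------------------------------------
# Region pair ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionPairScore:
    """A ranked enhancer-region x promoter-region attention pair.

    Both indices are merged indices (enhancer < L_enh <= promoter); the
    score is the mean of the two directional attention entries.
    """

    enhancer_region: int
    promoter_region: int
    score: float


def top_region_pairs(avg: np.ndarray, l_enh: int, k: int,
                     k_bounds: tuple[int, int] | None = (5, 8)) -> list[RegionPairScore]:
    """Top-k enhancer x promoter pairs from an averaged attention matrix.

    Candidates are restricted to the two cross blocks (enhancer rows x
    promoter columns and the transpose block); each candidate's score is the
    mean of its two directional entries.  Ties break by (enhancer index,
    promoter index) ascending.  ``k_bounds`` enforces the default 5..8
    policy; pass ``None`` (or widen the bounds) for an exhaustive ranked
    list over all candidates.
    """
    avg = np.asarray(avg)
    L = avg.shape[0]
    if avg.shape != (L, L) or not 0 < l_enh < L:
        raise InterpretError(f"bad attention matrix shape {avg.shape} or l_enh {l_enh}")
    n_prom = L - l_enh
    n_candidates = l_enh * n_prom
    if k_bounds is not None and not k_bounds[0] <= k <= k_bounds[1]:
        raise InterpretError(f"k={k} outside allowed bounds {k_bounds}")
    if k > n_candidates:
        raise InterpretError(f"k={k} exceeds candidate count {n_candidates}")
    cross = 0.5 * (avg[:l_enh, l_enh:] + avg[l_enh:, :l_enh].T)   # (l_enh, n_prom)
    flat = cross.ravel()
    # stable sort on (-score, enh, prom): row-major order is the tie order
    order = np.argsort(-flat, kind="stable")[:k]
    return [RegionPairScore(int(i // n_prom), int(l_enh + i % n_prom), float(flat[i]))
            for i in order]


# ---------------------------------------------------------------------------
# PWM extraction from conv/pool activations
# ---------------------------------------------------------------------------

@dataclass
class RegionPWM:
    """Nucleotide counts and frequencies for one merged region.

    ``counts`` is 4 x kernel_width (A, C, G, T rows); each column sums to
    ``n_sequences``.  ``freq`` applies the pseudocount:
    (count + pc) / (n + 4 pc), so frequency columns sum to 1.
    """

    r: int
    role: str
    counts: np.ndarray
    n_sequences: int
    pseudocount: float = 0.25

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def name(self) -> str:
        return f"{self.role}_region_{self.r}"

    @property
    def freq(self) -> np.ndarray:
        return (self.counts + self.pseudocount) / (self.n_sequences + 4.0 * self.pseudocount)


def extract_region_pwm(model_or_results, records: list[SequencePairRecord],
                       r: int, pseudocount: float = 0.25) -> RegionPWM:
    """Build the PWM for merged region r from positive samples.

    Per sample, the convolution/pooling stages are re-run on the relevant
    branch; within pool window r the conv position maximizing the
    per-position maximum over filters is selected, and the kernel-width raw
    window starting there is accumulated into base counts.
    """
    net = getattr(model_or_results, "network", model_or_results)
    cfg = net.cfg
    win = region_window(r, cfg)      # validates r
    L_enh = cfg.enh_pooled_len
    local = r if win.role == "enhancer" else r - L_enh
    start = local * cfg.pool_stride
    K = cfg.conv_kernel
    counts = np.zeros((4, K), dtype=np.int64)
    idx = {b: i for i, b in enumerate(BASES)}
    for rec in records:
        seq = rec.enhancer if win.role == "enhancer" else rec.promoter
        x = net.encode_batch([seq], win.role)
        act = net.branch_conv_activations(x, win.role)[0]      # (L_conv, F)
        window = act[start:start + cfg.pool_size]
        j_star = start + int(window.max(axis=1).argmax())
        if cfg.encoding == "dna2vec":
            # conv positions index tokens; token j starts at base j
            raw = seq[j_star:j_star + K + cfg.kmer_k - 1]
        else:
            raw = seq[j_star:j_star + K]
        for offset, base in enumerate(raw[:K]):
            if base in idx:
                counts[idx[base], offset] += 1
    return RegionPWM(r, win.role, counts, n_sequences=len(records), pseudocount=pseudocount)


def pwm_correlation(freq: np.ndarray, target: np.ndarray,
                    min_overlap: int | None = None) -> float:
    """Best-alignment mean per-column Pearson correlation of two PWMs.

    All relative shifts with at least ``min_overlap`` aligned columns are
    scanned (default: half the narrower matrix, as motif comparison tools
    do, since a convolution kernel's preferred phase need not center the
    motif); the score of a shift is the mean over its aligned columns of
    the Pearson correlation between the 4-base frequency vectors.  Columns
    with zero variance in either matrix contribute 0.
    """
    freq = np.asarray(freq, dtype=float)
    target = np.asarray(target, dtype=float)
    if freq.shape[1] < target.shape[1]:
        freq, target = target, freq
    w, m = freq.shape[1], target.shape[1]
    if min_overlap is None:
        min_overlap = max(1, m // 2)

    def col_r(a, b):
        sa, sb = a.std(), b.std()
        if sa < 1e-12 or sb < 1e-12:
            return 0.0
        return float(np.dot(a - a.mean(), b - b.mean()) / (4 * sa * sb))

    best = -1.0
    for off in range(-(m - min_overlap), w - min_overlap + 1):
        cols = [(off + j, j) for j in range(m) if 0 <= off + j < w]
        if len(cols) < min_overlap:
            continue
        score = float(np.mean([col_r(freq[:, i], target[:, j]) for i, j in cols]))
        best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# MEME motif format (minimal dialect)
# ---------------------------------------------------------------------------

def write_meme(pwms: list[RegionPWM], path) -> None:
    """Write PWMs as a minimal MEME motif file (version header, ACGT
    alphabet, + strand, uniform background, one letter-probability matrix
    per region)."""
    if not pwms:
        raise InterpretError("no PWMs to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25000 C 0.25000 G 0.25000 T 0.25000\n\n")
        for pwm in pwms:
            freq = pwm.freq
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= {pwm.n_sequences} E= 0\n")
            for j in range(pwm.width):
                fh.write(" " + " ".join(f"{freq[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, np.ndarray]:
    """Read the dialect written by :func:`write_meme`: name -> 4 x w
    frequency matrix (rows A, C, G, T)."""
    motifs: dict[str, np.ndarray] = {}
    name, rows = None, []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    motifs[name] = np.array(rows).T
                name, rows = line.split(maxsplit=1)[1].split()[0], []
            elif line.startswith("letter-probability"):
                continue
            elif name is not None and line and re.match(r"^[\d.eE+\- ]+$", line):
                vals = [float(v) for v in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
            elif not line and name is not None and rows:
                motifs[name] = np.array(rows).T
                name, rows = None, []
    if name is not None and rows:
        motifs[name] = np.array(rows).T
    return motifs


# ---------------------------------------------------------------------------
# TOMTOM results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """One retained motif-comparison hit for a query region PWM."""

    query: str
    target: str
    p_value: float
    e_value: float
    source: str = "tomtom"


_TOMTOM_ALIASES = {
    "query": ("Query_ID", "Query ID", "#Query ID"),
    "target": ("Target_ID", "Target ID"),
    "p": ("p-value", "p_value", "P-value"),
    "e": ("E-value", "e-value", "E_value"),
}


def read_tomtom(path, e_max: float = 0.07, p_max: float = 1e-4) -> list[MotifHit]:
    """Parse a TOMTOM result TSV, keeping hits with e-value < e_max and
    p-value < p_max.  Trailing '#' comment lines are ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    rows = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        return []
    header = rows[0].split("\t")
    cols = {}
    for key, aliases in _TOMTOM_ALIASES.items():
        for alias in aliases:
            if alias in header:
                cols[key] = header.index(alias)
                break
    missing = [k for k in _TOMTOM_ALIASES if k not in cols]
    if missing:
        raise InterpretError(f"TOMTOM file {path} missing required columns for {missing}; "
                             f"header was {header}")
    hits, dropped = [], 0
    for row in rows[1:]:
        parts = row.split("\t")
        if len(parts) <= max(cols.values()):
            dropped += 1
            continue
        p, e = float(parts[cols["p"]]), float(parts[cols["e"]])
        if e < e_max and p < p_max:
            hits.append(MotifHit(parts[cols["query"]], parts[cols["target"]], p, e))
        else:
            dropped += 1
    logger.info("tomtom %s: kept %d hits, dropped %d", path, len(hits), dropped)
    return hits


# ---------------------------------------------------------------------------
# BioGRID TAB export
# ---------------------------------------------------------------------------

class BioGridLookup:
    """Order-insensitive gene-symbol-pair -> evidence-type mapping."""

    def __init__(self, pairs: dict[frozenset, set[str]]):
        self._pairs = pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def evidence(self, tf_a: str, tf_b: str) -> set[str]:
        key = frozenset((tf_a.upper(), tf_b.upper()))
        return set(self._pairs.get(key, {"unvalidated"}))


def read_biogrid(path) -> BioGridLookup:
    """Parse a BioGRID TAB export (tab-delimited; needs the two official
    gene-symbol columns and Experimental System Type).  Malformed rows are
    skipped with logged line numbers; duplicates deduplicate; system types
    other than physical/genetic map to "indirect"."""
    pairs: dict[frozenset, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            return BioGridLookup({})
        header = [h.strip() for h in header_line.lstrip("#").rstrip("\n").split("\t")]
        low = [h.lower() for h in header]

        def find(*needles):
            for i, h in enumerate(low):
                if all(n in h for n in needles):
                    return i
            raise InterpretError(f"BioGRID file {path} lacks a column matching {needles}")

        ia = find("official symbol", "interactor a")
        ib = find("official symbol", "interactor b")
        ity = find("experimental system type")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(ia, ib, ity) or not parts[ia] or not parts[ib]:
                logger.warning("biogrid %s:%d: malformed row skipped", path, lineno)
                continue
            sys_type = parts[ity].strip().lower()
            ev = sys_type if sys_type in ("physical", "genetic") else "indirect"
            pairs.setdefault(frozenset((parts[ia].upper(), parts[ib].upper())), set()).add(ev)
    return BioGridLookup(pairs)


# ---------------------------------------------------------------------------
# Interaction table
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# Ground-truth recovery scoring (synthetic datasets)
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """How well the attention pipeline recovered a planted motif pair.

    ``overlap_fraction`` is the fraction of positive test samples whose own
    head-averaged top-k region pairs include one whose enhancer and promoter
    receptive fields both overlap that sample's planted windows.
    ``enh_pwm`` aggregates, over those supporting samples, the extracted
    kernel-width window at each sample's overlapping enhancer region;
    ``enh_pwm_correlation`` is its best-alignment mean per-column Pearson
    against the planted motif's expected PWM (promoter likewise).
    """

    n_samples: int
    n_supporting: int
    overlap_fraction: float
    enh_pwm: RegionPWM | None
    prom_pwm: RegionPWM | None
    enh_pwm_correlation: float
    prom_pwm_correlation: float


def _overlaps(win: RegionWindow, start: int, end: int) -> bool:
    return win.start < end and start < win.end


def evaluate_motif_recovery(model_or_results, positive_records, manifest,
                            k: int = 8) -> RecoveryReport:
    """Score planted-motif recovery on positive test samples of a synthetic
    dataset with a ground-truth manifest.

    For each sample the per-sample head-averaged attention matrix is ranked
    into top-k cross-block pairs; the sample supports recovery when some
    pair's receptive fields overlap both of its planted windows.  For
    supporting samples the strongest-activation kernel window at the
    overlapping enhancer (and promoter) region is accumulated into a PWM and
    correlated with the planted motif's expected PWM.
    """
    net = getattr(model_or_results, "network", model_or_results)
    cfg = net.cfg
    L_enh = cfg.enh_pooled_len
    maps = capture_attention(net, positive_records)
    K = cfg.conv_kernel
    counts = {"enhancer": np.zeros((4, K), dtype=np.int64),
              "promoter": np.zeros((4, K), dtype=np.int64)}
    n_sup = 0
    for i, rec in enumerate(positive_records):
        plant = manifest.plant_for(rec.id)
        e0 = plant.enh_position
        e1 = e0 + len(manifest.enh_motif)
        p0 = plant.prom_position
        p1 = p0 + len(manifest.prom_motif)
        pairs = top_region_pairs(average_heads(maps[i]), L_enh, k)
        for pair in pairs:
            we = region_window(pair.enhancer_region, cfg)
            wp = region_window(pair.promoter_region, cfg)
            if _overlaps(we, e0, e1) and _overlaps(wp, p0, p1):
                counts["enhancer"] += extract_region_pwm(net, [rec], pair.enhancer_region).counts
                counts["promoter"] += extract_region_pwm(net, [rec], pair.promoter_region).counts
                n_sup += 1
                break
    report = RecoveryReport(
        n_samples=len(positive_records), n_supporting=n_sup,
        overlap_fraction=n_sup / len(positive_records),
        enh_pwm=None, prom_pwm=None,
        enh_pwm_correlation=float("nan"), prom_pwm_correlation=float("nan"))
    if n_sup:
        report.enh_pwm = RegionPWM(-1, "enhancer", counts["enhancer"], n_sup)
        report.prom_pwm = RegionPWM(-1, "promoter", counts["promoter"], n_sup)
        report.enh_pwm_correlation = pwm_correlation(
            report.enh_pwm.freq, manifest.enh_motif.expected_pwm())
        report.prom_pwm_correlation = pwm_correlation(
            report.prom_pwm.freq, manifest.prom_motif.expected_pwm())
    return report


@dataclass
class InteractionRecord:
    """A TF(enhancer) x TF(promoter) interaction with its supporting cells
    and evidence annotations."""

    tf_enhancer: str
    tf_promoter: str
    cells: set[str] = field(default_factory=set)
    evidence: set[str] = field(default_factory=lambda: {"unvalidated"})


def best_hit_by_query(hits: list[MotifHit]) -> dict[str, MotifHit]:
    """Lowest-e-value retained hit per query region."""
    best: dict[str, MotifHit] = {}
    for h in hits:
        if h.query not in best or h.e_value < best[h.query].e_value:
            best[h.query] = h
    return best


def build_interaction_table(
        pairs_per_cell: dict[str, list[RegionPairScore]],
        hits_per_cell: dict[str, list[MotifHit]],
        cfg: ModelConfig,
        biogrid: BioGridLookup | None = None,
) -> tuple[list[InteractionRecord], list[tuple[str, RegionPairScore]]]:
    """Join top region pairs with per-region TF assignments into a table of
    TF(enhancer) x TF(promoter) interactions.

    A pair contributes only when both its regions carry a retained motif
    hit; others are returned in the unassigned side list.  Records aggregate
    across cells into explicit cell sets, and a BioGRID lookup (if given)
    annotates evidence types by order-insensitive symbol pair.
    """
    table: dict[tuple[str, str], InteractionRecord] = {}
    unassigned: list[tuple[str, RegionPairScore]] = []
    for cell, pairs in pairs_per_cell.items():
        assignment = best_hit_by_query(hits_per_cell.get(cell, []))
        for pair in pairs:
            qe = region_window(pair.enhancer_region, cfg).name
            qp = region_window(pair.promoter_region, cfg).name
            he, hp = assignment.get(qe), assignment.get(qp)
            if he is None or hp is None:
                unassigned.append((cell, pair))
                continue
            key = (he.target, hp.target)
            rec = table.setdefault(key, InteractionRecord(he.target, hp.target, set()))
            rec.cells.add(cell)
    records = list(table.values())
    if biogrid is not None:
        for rec in records:
            rec.evidence = biogrid.evidence(rec.tf_enhancer, rec.tf_promoter)
    records.sort(key=lambda r: (-len(r.cells), r.tf_enhancer, r.tf_promoter))
    return records, unassigned
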