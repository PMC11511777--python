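"""Synthetic amplicon-read simulator with known per-cytosine editing.

The generative model is a two-level mixture that mimics heteroplasmic
editing of a multicopy mitochondrial genome:

1. Each sequenced molecule is *edited* with probability ``f`` (the
   edited-molecule fraction — the heteroplasmy-like level installed by
   the editor).
2. On an edited molecule, each spacer cytosine ``i`` deaminates
   independently with conditional probability ``q_i``; the marginal
   per-site edit probability is therefore ``p_i = f * q_i``.
3. Every C/G position *outside* the spacer converts with a small
   background probability ``b`` on all molecules (deaminase action
   without TALE guidance).
4. A uniform sequencing substitution error ``e`` finally replaces each
   base with one of the three alternatives with probability ``e``.

The mixture (rather than independent Bernoulli sites) matters: both
deaminase processivity and heteroplasmy put *correlated* edits on the
same molecule, which makes the read-level "any conversion in the
spacer" statistic distinguishable from per-site marginals.

Conversions are strand-faithful: a top-strand C reads T, a bottom-
strand C (top-strand G) reads A.  Default parameters are chosen to
emulate the observable scale of dimeric-editor amplicon data: marginal
on-target editing in the tens of percent (``f = 0.5``, ``q0 = 0.5``),
background conversion of a few per mille (``b = 0.002``), and an
Illumina-like substitution error of 0.1%.  Indels, quality-dependent
errors and coverage unevenness are deliberately not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genome_model import CytosineSite, EditorPair, SequenceRecord, spacer_cytosines
from .io import Read, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: alternatives[b] = the three bases != b, used for substitution errors
_ALTERNATIVES = {b: [x for x in b"ACGT" if x != b] for b in b"ACGT"}


def default_context_multipliers(deaminase: str) -> tuple[float, float]:
    """(m_TC, m_nonTC) conditional-rate multipliers for a deaminase.

    DddAtox and DddA6 strongly prefer TC dinucleotides; DddA11 processes
    non-TC cytosines at a substantial relative rate.
    """
    if deaminase == "DddA11":
        return (1.0, 0.6)
    return (1.0, 0.1)


@dataclass(frozen=True)
class SimulationParams:
    """User-facing knobs of the generative model (see module docstring)."""

    f: float = 0.5            # edited-molecule fraction
    q0: float = 0.5           # base conditional edit rate at TC sites
    m_tc: Optional[float] = None      # context multipliers; None = per-deaminase default
    m_nontc: Optional[float] = None
    b: float = 0.002          # background conversion per off-spacer C/G
    e: float = 0.001          # uniform substitution error per base
    n_reads: int = 20_000
    seed: int = 0
    indel_rate: float = 0.0   # reserved; indels are not simulated by default

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ParameterError(f"edited-molecule fraction f={self.f} outside [0, 1]")
        if not 0.0 <= self.q0 <= 1.0:
            raise ParameterError(f"base conditional rate q0={self.q0} outside [0, 1]")
        if not 0.0 <= self.b < 1.0:
            raise ParameterError(f"background rate b={self.b} outside [0, 1)")
        if not 0.0 <= self.e <= 0.05:
            raise ParameterError(f"substitution error e={self.e} outside [0, 0.05]")
        if self.n_reads < 1:
            raise ParameterError("n_reads must be >= 1")
        if self.indel_rate != 0.0:
            raise ParameterError("indel simulation is not implemented (indel_rate must be 0)")


@dataclass
class SimulationTruth:
    """Fully resolved ground truth: who edits what, at which rate."""

    rec: SequenceRecord
    pair: EditorPair
    sites: list[CytosineSite]          # spacer cytosines, ordered by position
    q: dict[int, float]                # top_pos -> conditional edit prob on edited molecules
    f: float
    b: float
    e: float
    n_reads: int
    seed: int
    offspacer_cg: list[int] = field(default_factory=list)  # off-spacer C/G top positions

    def marginal(self, top_pos: int) -> float:
        """Marginal edit probability p_i at a reference C/G position."""
        if top_pos in self.q:
            return self.f * self.q[top_pos]
        if top_pos in self.offspacer_cg:
            return self.b
        raise KeyError(f"position {top_pos} is not a C/G position of the amplicon")

    def params_json(self) -> str:
        return json.dumps(
            {
                "f": self.f,
                "b": self.b,
                "e": self.e,
                "n_reads": self.n_reads,
                "seed": self.seed,
                "q": {str(k): v for k, v in self.q.items()},
                "pair": self.pair.to_dict(),
            },
            indent=2,
        )

    def site_table(self) -> pd.DataFrame:
        """Per-site marginal truth (position, strand, C_k, p_i)."""
        rows = [
            {
                "position": s.top_pos,
                "strand": s.c_strand,
                "spacer_index": s.spacer_index,
                "is_TC": s.is_TC,
                "q": self.q[s.top_pos],
                "p_marginal": self.f * self.q[s.top_pos],
            }
            for s in self.sites
        ]
        return pd.DataFrame(rows)


def build_truth(
    rec: SequenceRecord, pair: EditorPair, params: SimulationParams
) -> SimulationTruth:
    """Resolve per-site conditional rates from base rate and context.

    ``q_i = clamp(q0 * m_context(deaminase, is_TC_i), 0, 1)``, with the
    TC/non-TC multipliers defaulting per deaminase variant.
    """
    m_tc, m_nontc = default_context_multipliers(pair.deaminase)
    if params.m_tc is not None:
        m_tc = params.m_tc
    if params.m_nontc is not None:
        m_nontc = params.m_nontc
    if m_tc < 0 or m_nontc < 0:
        raise ParameterError("context multipliers must be non-negative")
    sites = spacer_cytosines(pair, rec)
    q = {
        s.top_pos: min(max(params.q0 * (m_tc if s.is_TC else m_nontc), 0.0), 1.0)
        for s in sites
    }
    spacer = set(range(*pair.spacer))
    offspacer = [i for i, base in enumerate(rec.seq) if base in "CG" and i not in spacer]
    return SimulationTruth(
        rec=rec,
        pair=pair,
        sites=sites,
        q=q,
        f=params.f,
        b=params.b,
        e=params.e,
        n_reads=params.n_reads,
        seed=params.seed,
        offspacer_cg=offspacer,
    )


@dataclass
class SimulationResult:
    """Reads plus the per-molecule truth needed for oracle-style checks."""

    truth: SimulationTruth
    reads: list[Read]
    edited: np.ndarray              # (n,) bool: molecule drew the edited state
    conversions: np.ndarray         # (n, n_sites) bool: spacer site converted
    background: np.ndarray          # (n, n_offspacer) bool: off-spacer conversion

    def truth_base_matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix of pre-error molecule sequences.

        Built directly from the truth matrices, independent of the read
        strings and of any alignment — the direct-counting oracle for
        the FASTQ -> align -> tables pipeline.
        """
        t = self.truth
        n = t.n_reads
        ref = np.frombuffer(t.rec.seq.encode(), dtype=np.uint8)
        mat = np.tile(ref, (n, 1))
        for j, s in enumerate(t.sites):
            conv = ord("T") if s.c_strand == "top" else ord("A")
            mat[self.conversions[:, j], s.top_pos] = conv
        for j, pos in enumerate(t.offspacer_cg):
            conv = ord("T") if t.rec.seq[pos] == "C" else ord("A")
            mat[self.background[:, j], pos] = conv
        return mat

    def truth_spacer_alleles(self) -> pd.DataFrame:
        """Spacer allele counts computed from the truth matrices."""
        start, end = self.truth.pair.spacer
        mat = self.truth_base_matrix()[:, start:end]
        alleles = ["".join(chr(c) for c in row) for row in mat]
        counts = pd.Series(alleles).value_counts()
        df = counts.rename_axis("allele").reset_index(name="count")
        df["fraction"] = df["count"] / len(alleles)
        return df

    def molecule_table(self) -> pd.DataFrame:
        """Per-molecule truth sidecar (edited flag + converted positions)."""
        t = self.truth
        site_pos = [s.top_pos for s in t.sites]
        rows = []
        for i in range(t.n_reads):
            conv = [site_pos[j] for j in range(len(site_pos)) if self.conversions[i, j]]
            bg = [t.offspacer_cg[j] for j in range(len(t.offspacer_cg)) if self.background[i, j]]
            rows.append(
                {
                    "molecule": i,
                    "edited": bool(self.edited[i]),
                    "spacer_conversions": ",".join(map(str, conv)),
                    "background_conversions": ",".join(map(str, bg)),
                }
            )
        return pd.DataFrame(rows)

    def write(self, fastq_path, sidecar_prefix=None) -> None:
        """Write FASTQ (and optional sidecar TSV/JSON truth files)."""
        write_fastq(self.reads, fastq_path)
        if sidecar_prefix is not None:
            prefix = Path(sidecar_prefix)
            self.truth.site_table().to_csv(prefix.with_suffix(".sites.tsv"), sep="\t", index=False)
            self.molecule_table().to_csv(
                prefix.with_suffix(".molecules.tsv"), sep="\t", index=False
            )
            prefix.with_suffix(".params.json").write_text(self.truth.params_json())


def simulate_reads(truth: SimulationTruth) -> SimulationResult:
    """Draw reads from the mixture model; byte-reproducible from the seed.

    Read names encode the molecule index and edited status for
    debugging only — the quantifier never reads them.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_reads
    L = len(truth.rec)

    edited = rng.random(n) < truth.f
    n_sites = len(truth.sites)
    conversions = np.zeros((n, n_sites), dtype=bool)
    for j, s in enumerate(truth.sites):
        conversions[:, j] = edited & (rng.random(n) < truth.q[s.top_pos])
    background = rng.random((n, len(truth.offspacer_cg))) < truth.b

    result = SimulationResult(truth, [], edited, conversions, background)
    mat = result.truth_base_matrix()

    if truth.e > 0:
        err = rng.random((n, L)) < truth.e
        idx = np.argwhere(err)
        choices = rng.integers(0, 3, size=len(idx))
        for (i, j), k in zip(idx, choices):
            mat[i, j] = _ALTERNATIVES[mat[i, j]][k]

    qual = "I" * L
    reads = [
        Read(f"mol{i}|edited={int(edited[i])}", row.tobytes().decode("ascii"), qual)
        for i, row in enumerate(mat)
    ]
    result.reads = reads
    return result


def expected_observed_rate(p: float, e: float) -> float:
    """Expected converted-base frequency at a reference C/G position.

    A position edits with marginal probability ``p``; sequencing error
    then either destroys a real conversion (prob ``e``) or fakes one
    (prob ``e/3``): ``p*(1-e) + (1-p)*e/3``.
    """
    if not 0.0 <= p <= 1.0 or not 0.0 <= e <= 1.0:
        raise ParameterError("p and e must lie in [0, 1]")
    return p * (1.0 - e) + (1.0 - p) * e / 3.0


def random_amplicon(
    length: int = 220,
    gc: float = 0.44,
    seed: int = 0,
    id: str = "synthetic_amplicon",
    ref_offset: Optional[int] = None,
) -> SequenceRecord:
    """A reproducible random amplicon at mtDNA-like GC content (~44%)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return SequenceRecord(id, seq, ref_offset)
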