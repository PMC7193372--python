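"""Synthetic inputs with planted ground truth.

Every downstream stage of the pipeline — mimicry screening, functional
read-count profiling, O-PLS metabolite association and cohort statistics
— is exercisable on data generated here, with the planted truth returned
alongside so recovery can be checked exactly:

* a reference "ClpB-like" protein carrying the epitope motif;
* ORF populations per bacterial family with a controlled number of
  substitutions inside the motif copy and a controlled per-residue
  flank identity (substitutions always change the residue, so the flank
  identity is an exact per-residue match probability and expectations
  are analytic);
* a toy annotated metagenome (homology-hit, ORF-location and
  read-alignment tables) in which every real ORF carries a best hit to
  one KEGG ortholog and, with probability 0.3, a strictly inferior
  decoy hit, so best-hit selection is exercised;
* a metabolite matrix with one y-predictive latent component plus
  y-orthogonal components; and
* a cohort table with a planted function-abundance/adiposity
  correlation.

All randomness flows from a single integer seed through a named
``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AMINO_ACIDS, validate_protein
from .mimicry import DEFAULT_FLANK, DEFAULT_MOTIF, ReferenceProtein

#: KEGG ortholog of the ATP-dependent chaperone ClpB.
CLPB_KO = "K03695"
#: BMI threshold (kg/m^2) defining the obesity group.
OBESITY_BMI_THRESHOLD = 30.0


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one bacterial family's ORF population.

    ``motif_mismatches`` substitutions are planted inside each ORF's
    copy of the motif; each flank residue independently matches the
    reference with probability ``flank_identity``.
    """

    family_name: str
    n_orfs: int
    motif_mismatches: int = 0
    flank_identity: float = 1.0

    def __post_init__(self) -> None:
        if self.n_orfs < 0:
            raise ValueError("n_orfs must be >= 0")
        if self.motif_mismatches < 0:
            raise ValueError("motif_mismatches must be >= 0")
        if not 0.0 <= self.flank_identity <= 1.0:
            raise ValueError("flank_identity must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators."""

    full_motif_counts: Dict[str, int] = field(default_factory=dict)
    expected_flank_identity: Dict[str, float] = field(default_factory=dict)
    reads_per_ko: Dict[str, Dict[str, int]] = field(default_factory=dict)
    decoy_reads: Dict[str, int] = field(default_factory=dict)
    latent: Dict[str, object] = field(default_factory=dict)
    cohort_effect_r: Optional[float] = None


def make_reference(
    seed: int,
    length: int = 600,
    motif: str = DEFAULT_MOTIF,
    motif_position: int = 300,
) -> ReferenceProtein:
    """Random reference protein with ``motif`` planted at ``motif_position``.

    ``motif_position`` is 1-based; residues outside the motif are drawn
    uniformly from the 20 standard amino acids.  Deterministic given the
    seed.
    """
    validate_protein(motif, "motif")
    if not 1 <= motif_position <= length - len(motif) + 1:
        raise ValueError(
            f"motif_position {motif_position} does not fit a length-{len(motif)} "
            f"motif into a length-{length} sequence"
        )
    rng = np.random.default_rng(seed)
    residues = rng.choice(list(AMINO_ACIDS), size=length)
    seq = list("".join(residues))
    seq[motif_position - 1 : motif_position - 1 + len(motif)] = motif
    return ReferenceProtein(
        id="synthetic_clpb_like_ref",
        accession="SYN_CLPB_0001.1",
        sequence="".join(seq),
        motif_start=motif_position,
        motif_end=motif_position + len(motif) - 1,
    )


def _substitute(rng: np.random.Generator, residue: str) -> str:
    """A residue different from ``residue``, uniform over the 19 others."""
    alternatives = AMINO_ACIDS.replace(residue, "")
    return alternatives[int(rng.integers(len(alternatives)))]


def make_orf_population(
    reference: ReferenceProtein,
    specs: Sequence[FamilySpec],
    flank_span: int = DEFAULT_FLANK,
    seed: int = 0,
) -> Tuple[List[SeqRecord], Dict[str, str], SyntheticTruth]:
    """ORFs copied from the reference epitope window, mutated per family.

    Each ORF copies the reference window ``[motif_start - flank_span,
    motif_end + flank_span]`` (clipped at the sequence ends), plants
    exactly ``motif_mismatches`` substitutions at motif positions chosen
    without replacement, and retains each flank residue with probability
    ``flank_identity`` (substituting to a different residue otherwise).
    Returns (FASTA records, orf_id -> family map, truth).
    """
    if flank_span < 0:
        raise ValueError("flank_span must be >= 0")
    if not specs:
        raise ValueError("at least one FamilySpec is required")
    motif_len = reference.motif_end - reference.motif_start + 1
    for spec in specs:
        if spec.motif_mismatches > motif_len:
            raise ValueError(
                f"{spec.family_name}: motif_mismatches ({spec.motif_mismatches}) "
                f"exceeds motif length ({motif_len})"
            )

    rng = np.random.default_rng(seed)
    win_lo = max(1, reference.motif_start - flank_span)
    win_hi = min(len(reference.sequence), reference.motif_end + flank_span)
    window = reference.sequence[win_lo - 1 : win_hi]
    motif_idx = list(range(reference.motif_start - win_lo, reference.motif_end - win_lo + 1))
    flank_idx = [i for i in range(len(window)) if i not in set(motif_idx)]

    records: List[SeqRecord] = []
    taxonomy: Dict[str, str] = {}
    truth = SyntheticTruth()
    for spec in specs:
        full = 0
        truth.expected_flank_identity[spec.family_name] = spec.flank_identity
        for k in range(spec.n_orfs):
            seq = list(window)
            if spec.motif_mismatches:
                sites = rng.choice(motif_idx, size=spec.motif_mismatches, replace=False)
                for s in sites:
                    seq[s] = _substitute(rng, seq[s])
            keep = rng.random(len(flank_idx)) < spec.flank_identity
            for pos, kept in zip(flank_idx, keep):
                if not kept:
                    seq[pos] = _substitute(rng, seq[pos])
            orf_id = f"{spec.family_name}_orf{k:04d}"
            records.append(
                SeqRecord(Seq("".join(seq)), id=orf_id, description=f"family={spec.family_name}")
            )
            taxonomy[orf_id] = spec.family_name
            if all(seq[i] == window[i] for i in motif_idx):
                full += 1
        truth.full_motif_counts[spec.family_name] = full
    return records, taxonomy, truth


ReadsPerOrf = Union[int, Mapping[str, int], Callable[[np.random.Generator], int]]


def make_metagenome(
    orfs: Sequence,
    reads_per_orf: ReadsPerOrf,
    n_decoy_orfs: int = 0,
    ko_for_hits: str = CLPB_KO,
    seed: int = 0,
    *,
    n_samples: int = 1,
    read_length: int = 100,
    decoy_ko: str = "K99999",
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Toy annotated metagenome around the supplied protein ORFs.

    Each real ORF sits on its own contig (nucleotide span = 3 x protein
    length at a random offset) and receives one homology hit to
    ``ko_for_hits`` plus, with probability 0.3, a strictly inferior hit
    (higher e-value, lower bitscore) to ``decoy_ko``.  Decoy ORFs get
    reads but no hits, so the profiling stage must drop them.  Read
    alignments always fall inside their ORF's span.  Returns
    (hits, orf locations, read alignments, truth); read rows carry a
    ``sample`` column.
    """
    if n_decoy_orfs < 0:
        raise ValueError("n_decoy_orfs must be >= 0")
    rng = np.random.default_rng(seed)

    def draw_reads(orf_id: str) -> int:
        if callable(reads_per_orf):
            k = int(reads_per_orf(rng))
        elif isinstance(reads_per_orf, Mapping):
            k = int(reads_per_orf.get(orf_id, 0))
        else:
            k = int(reads_per_orf)
        if k < 0:
            raise ValueError("reads per ORF must be >= 0")
        return k

    orf_entries: List[Tuple[str, int, bool]] = []  # (orf_id, aa length, is_decoy)
    for orf in orfs:
        orf_id, seq = (orf if isinstance(orf, tuple) else (orf.id, str(orf.seq)))
        orf_entries.append((orf_id, len(seq), False))
    for d in range(n_decoy_orfs):
        orf_entries.append((f"decoy{d:03d}", 100, True))

    hit_rows, loc_rows, read_rows = [], [], []
    truth = SyntheticTruth()
    samples = [f"S{s + 1}" for s in range(n_samples)]
    for s in samples:
        truth.reads_per_ko[s] = {ko_for_hits: 0}
        truth.decoy_reads[s] = 0

    for orf_id, aa_len, is_decoy in orf_entries:
        contig = f"ctg_{orf_id}"
        start = int(rng.integers(1, 51))
        end = start + 3 * aa_len - 1
        strand = "+" if rng.random() < 0.5 else "-"
        loc_rows.append((contig, start, end, strand, orf_id))
        if not is_decoy:
            evalue = 10.0 ** float(rng.uniform(-60, -20))
            bitscore = round(float(rng.uniform(200, 800)), 1)
            hit_rows.append((orf_id, ko_for_hits, evalue, bitscore))
            if rng.random() < 0.3:
                worse_evalue = evalue * 10.0 ** float(rng.uniform(2, 15))
                hit_rows.append(
                    (orf_id, decoy_ko, worse_evalue, round(bitscore * float(rng.uniform(0.3, 0.8)), 1))
                )
        for s in samples:
            k = draw_reads(orf_id)
            for r in range(k):
                if end - start + 1 <= read_length:
                    rs, re = start, end
                else:
                    rs = int(rng.integers(start, end - read_length + 2))
                    re = rs + read_length - 1
                read_rows.append((f"{s}_{orf_id}_r{r:03d}", contig, rs, re, s))
            if is_decoy:
                truth.decoy_reads[s] += k
            else:
                truth.reads_per_ko[s][ko_for_hits] += k

    hits = pd.DataFrame(hit_rows, columns=["orf_id", "ko", "evalue", "bitscore"])
    locations = pd.DataFrame(loc_rows, columns=["contig", "start", "end", "strand", "orf_id"])
    reads = pd.DataFrame(read_rows, columns=["read_id", "contig", "start", "end", "sample"])
    return hits, locations, reads, truth


def make_metabolome(
    n_samples: int,
    n_features: int,
    n_ortho: int = 1,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Metabolite matrix with one predictive and ``n_ortho`` orthogonal parts.

    ``X = t p' + sum_o t_o p_o' + E`` with the response ``y = t +
    noise``; each orthogonal score vector ``t_o`` is projected to be
    exactly orthogonal to ``t`` (and to earlier ``t_o``), and ``E`` is
    i.i.d. Gaussian with SD ``noise_sd``.
    """
    if n_samples <= n_ortho + 1:
        raise ValueError("need n_samples > n_ortho + 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n_samples)
    basis = [t]
    t_os, p_os = [], []
    for _ in range(n_ortho):
        z = rng.standard_normal(n_samples)
        for u in basis:
            z = z - (z @ u) / (u @ u) * u
        basis.append(z)
        t_os.append(z)
        p_os.append(rng.standard_normal(n_features))
    p = rng.standard_normal(n_features)
    X = np.outer(t, p)
    for t_o, p_o in zip(t_os, p_os):
        X += np.outer(t_o, p_o)
    X += noise_sd * rng.standard_normal((n_samples, n_features))
    y = t + noise_sd * rng.standard_normal(n_samples)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    feature_names = [f"met_{j + 1:03d}" for j in range(n_features)]
    truth = SyntheticTruth()
    truth.latent = {"t": t, "p": p, "T_o": np.array(t_os).T, "P_o": np.array(p_os).T,
                    "noise_sd": noise_sd}
    return (
        pd.DataFrame(X, index=sample_ids, columns=feature_names),
        pd.Series(y, index=sample_ids, name="function_abundance"),
        truth,
    )


def classify_obesity(bmi: float) -> str:
    """Group label from BMI: "obese" iff BMI >= 30 kg/m^2."""
    return "obese" if bmi >= OBESITY_BMI_THRESHOLD else "nonobese"


def make_cohort(
    n: int,
    effect_r: float = -0.35,
    seed: int = 0,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Cohort metadata with a planted function-abundance/BMI correlation.

    ``function_abundance`` (relative abundance of the ClpB-like KO, on
    the ~0.15 scale of real per-sample fractions) and BMI are drawn from
    a bivariate normal with correlation ``effect_r``; the obesity group
    label follows the BMI >= 30 kg/m^2 convention.  Sex, age and energy
    intake are drawn independently at cohort-realistic scales.
    """
    if not abs(effect_r) < 1:
        raise ValueError("effect_r must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    z_bmi = effect_r * z1 + np.sqrt(1.0 - effect_r**2) * z2
    bmi = 32.0 + 8.0 * z_bmi
    function_abundance = 0.15 + 0.03 * z1
    table = pd.DataFrame(
        {
            "subject_id": [f"sub{i + 1:03d}" for i in range(n)],
            "sex": np.where(rng.random(n) < 0.68, "F", "M"),
            "age": np.round(rng.uniform(27.0, 67.0, size=n), 1),
            "bmi": bmi,
            "energy_intake": rng.normal(2100.0, 450.0, size=n),
            "function_abundance": function_abundance,
        }
    )
    table["group"] = [classify_obesity(b) for b in table["bmi"]]
    truth = SyntheticTruth()
    truth.cohort_effect_r = effect_r
    return table, truth
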