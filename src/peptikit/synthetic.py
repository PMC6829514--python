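"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the shape of a hydrolysate-screening study: a
handful of muscle-protein-sized sequences (default five proteins of
150-1900 residues, the scale of a myofibrillar protein panel), a catalogue
of short activity-annotated peptides, proteins with bioactive motifs
planted in cleavage-compatible flanking contexts, and noisy plate-assay
readouts with a known true inhibition fraction.

All randomness flows from one integer seed through numpy's PCG64
generator. Each operation draws from its own named substream derived from
the master seed, so adding an operation never perturbs another's draws and
results are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import CatalogueEntry, PeptideCatalogue
from .io_formats import CANONICAL_RESIDUES, ProteinRecord, validate_sequence
from .proteolysis import Enzyme, digest

_ALPHABET = sorted(CANONICAL_RESIDUES)

#: Fixed substream indices; append only, never reorder.
_STREAMS = {"proteins": 0, "planting": 1, "assay_ace": 2, "assay_dppiv": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror a five-protein myofibrillar panel with uniform residue
    composition and plate-reader noise of 0.02 absorbance units.
    """

    seed: int = 0
    n_proteins: int = 5
    length_range: tuple[int, int] = (150, 1900)
    composition: dict[str, float] | None = None
    planted: tuple[tuple[str, str], ...] = ()  # (peptide, activity)
    n_copies: int = 3
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length_range {self.length_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.composition is not None:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition sums to {total}, not 1")
            bad = set(self.composition) - CANONICAL_RESIDUES
            if bad:
                raise ValueError(f"non-canonical residues in composition: {bad}")
            if any(p < 0 for p in self.composition.values()):
                raise ValueError("composition probabilities must be >= 0")
        for peptide, _ in self.planted:
            validate_sequence(peptide)


def _probabilities(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    if spec.composition is None:
        return _ALPHABET, np.full(len(_ALPHABET), 1.0 / len(_ALPHABET))
    residues = sorted(spec.composition)
    return residues, np.asarray([spec.composition[r] for r in residues])


def random_proteins(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Random background proteins with the spec's length and composition."""
    rng = _rng(spec.seed, "proteins")
    residues, probs = _probabilities(spec)
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        records.append(ProteinRecord(
            identifier=f"SYN{i + 1:04d}",
            description=f"synthetic protein (seed={spec.seed})",
            sequence=seq))
    return records


def random_sequence(length: int, rng: np.random.Generator,
                    composition: dict[str, float] | None = None) -> str:
    """One random sequence; helper for property tests."""
    if composition is None:
        return "".join(rng.choice(_ALPHABET, size=length))
    residues = sorted(composition)
    probs = np.asarray([composition[r] for r in residues])
    return "".join(rng.choice(residues, size=length, p=probs))


# ---------------------------------------------------------------------------
# Motif planting

class PlantingError(ValueError):
    """The motif cannot be released intact by the enzyme."""


def _p1_candidates(enzyme: Enzyme, p1prime: str) -> list[str]:
    """Residues that, placed at P1 before *p1prime*, trigger cleavage."""
    out = []
    for r in sorted(CANONICAL_RESIDUES):
        if enzyme.cleaves(r, p1prime, None):
            out.append(r)
    return out


def plant_releasable(protein: ProteinRecord, motif: str, enzyme: Enzyme,
                     position: int,
                     rng: np.random.Generator | None = None) -> ProteinRecord:
    """Insert *motif* so that a complete digest releases it intact.

    The motif is inserted after ``position`` residues (0-based offset into
    the parent sequence) together with two flanking residues: a left flank
    drawn from the residues the enzyme accepts at P1 before the motif's
    first residue, and a right flank accepted at P1' after the motif's
    last residue. The construction is then verified by digesting the
    returned protein.

    Raises
    ------
    PlantingError
        If the motif contains an internal cleavage site (it could never be
        released intact), if no admissible flank exists (e.g. the motif
        starts with a residue the enzyme refuses at P1', or its last
        residue is not cleavable at P1), or if *position* is out of range.
    """
    motif = validate_sequence(motif)
    if not (0 <= position <= len(protein)):
        raise PlantingError(f"position {position} outside 0..{len(protein)}")
    rng = rng or np.random.default_rng(0)

    internal = [i for i in range(1, len(motif))
                if enzyme.cleaves(motif[i - 1], motif[i],
                                  motif[i - 2] if i >= 2 else None)]
    if internal:
        raise PlantingError(
            f"motif {motif!r} is internally cleavable at bond(s) {internal}; "
            "it would never be released intact")

    left_options = _p1_candidates(enzyme, motif[0])
    if not left_options:
        raise PlantingError(
            f"no residue can trigger cleavage before {motif[0]!r} "
            f"(motif N-terminus) with enzyme {enzyme.name!r}")
    right_options = [r for r in sorted(CANONICAL_RESIDUES)
                     if enzyme.cleaves(motif[-1], r,
                                       motif[-2] if len(motif) >= 2 else None)]
    if not right_options:
        raise PlantingError(
            f"motif C-terminal residue {motif[-1]!r} is not cleavable at P1 "
            f"by enzyme {enzyme.name!r}; the motif cannot be released "
            "except at a protein C-terminus")

    left = left_options[int(rng.integers(len(left_options)))]
    right = right_options[int(rng.integers(len(right_options)))]
    seq = protein.sequence
    new_seq = seq[:position] + left + motif + right + seq[position:]
    planted = ProteinRecord(
        identifier=protein.identifier,
        description=protein.description, sequence=new_seq)

    released = {f.sequence for f in digest(planted, enzyme)}
    if motif not in released:
        raise PlantingError(
            f"verification failed: digest of the planted protein does not "
            f"release {motif!r} (flanks {left!r}/{right!r})")
    return planted


def plant_copies(protein: ProteinRecord, motif: str, enzyme: Enzyme,
                 n_copies: int, rng: np.random.Generator,
                 max_attempts: int = 50) -> ProteinRecord:
    """Plant *n_copies* of a motif at random offsets.

    After each insertion the digest is re-run and the number of released
    motif instances checked, so an insertion that happens to land inside an
    earlier copy (destroying it) is rejected and redrawn.
    """
    out = protein
    for copy in range(1, n_copies + 1):
        for _ in range(max_attempts):
            position = int(rng.integers(0, len(out) + 1))
            candidate = plant_releasable(out, motif, enzyme, position, rng=rng)
            released = sum(1 for f in digest(candidate, enzyme)
                           if f.sequence == motif)
            if released >= copy:
                out = candidate
                break
        else:
            raise PlantingError(
                f"could not place copy {copy} of {motif!r} in "
                f"{max_attempts} attempts")
    return out


def background_without_motifs(spec: SyntheticSpec, motifs: list[str],
                              max_attempts: int = 200) -> list[ProteinRecord]:
    """Background proteins rejection-sampled to exclude chance motif hits.

    Needed when exact planted-copy recovery is asserted: a motif occurring
    in the background by chance would inflate the recovered count.
    """
    rng = _rng(spec.seed, "proteins")
    residues, probs = _probabilities(spec)
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_proteins):
        for _ in range(max_attempts):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(residues, size=length, p=probs))
            if not any(m in seq for m in motifs):
                break
        else:
            raise RuntimeError(
                f"could not draw a background free of {motifs} in "
                f"{max_attempts} attempts; shorten the proteins or motifs")
        records.append(ProteinRecord(
            identifier=f"SYN{i + 1:04d}",
            description="synthetic background (motif-free)", sequence=seq))
    return records


# ---------------------------------------------------------------------------
# Assay simulation

#: Plate-model constants: FAPGG kinetic run (initial absorbance, control
#: endpoint drop over a 30-minute read) and p-nitroanilide endpoint levels.
_ACE_A0 = 1.0
_ACE_CONTROL_DROP = 0.45
_ACE_MINUTES = 30.0
_DPPIV_A_NEG = 0.05
_DPPIV_A_POS = 1.05
_DPPIV_A_BLANK = 0.05


def synthetic_assay(true_inhibition: float, n_replicates: int,
                    noise_sd: float, seed: int) -> dict[str, pd.DataFrame]:
    """Simulated ACE and DPP-IV plate readouts with known true inhibition.

    The noiseless readouts invert exactly to *true_inhibition* through the
    assay formulas; Gaussian noise of ``noise_sd`` (absorbance units) is
    then added to every simulated absorbance. Returns ``{"ace": ...,
    "dppiv": ...}`` DataFrames in the schemas the assay calculators read.
    """
    if not (0.0 <= true_inhibition <= 100.0):
        raise ValueError("true_inhibition must be in [0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    frac = true_inhibition / 100.0

    rng_ace = _rng(seed, "assay_ace")
    slope_control_true = -_ACE_CONTROL_DROP / _ACE_MINUTES
    slope_sample_true = slope_control_true * (1.0 - frac)
    rows_ace = []
    for i in range(n_replicates):
        # noise enters through the two endpoint absorbances of each well
        noise = rng_ace.normal(0.0, noise_sd, size=4)
        a_control = (_ACE_A0 + noise[0],
                     _ACE_A0 + slope_control_true * _ACE_MINUTES + noise[1])
        a_sample = (_ACE_A0 + noise[2],
                    _ACE_A0 + slope_sample_true * _ACE_MINUTES + noise[3])
        rows_ace.append({
            "replicate": i + 1,
            "slope_control": (a_control[1] - a_control[0]) / _ACE_MINUTES,
            "slope_sample": (a_sample[1] - a_sample[0]) / _ACE_MINUTES,
        })

    rng_dppiv = _rng(seed, "assay_dppiv")
    a_sample_true = _DPPIV_A_BLANK + (1.0 - frac) * (_DPPIV_A_POS - _DPPIV_A_NEG)
    rows_dppiv = []
    for i in range(n_replicates):
        noise = rng_dppiv.normal(0.0, noise_sd, size=4)
        rows_dppiv.append({
            "replicate": i + 1,
            "a_sample": a_sample_true + noise[0],
            "a_blank": _DPPIV_A_BLANK + noise[1],
            "a_pos_control": _DPPIV_A_POS + noise[2],
            "a_neg_control": _DPPIV_A_NEG + noise[3],
        })

    return {"ace": pd.DataFrame(rows_ace), "dppiv": pd.DataFrame(rows_dppiv)}


def planted_catalogue(planted: list[tuple[str, str]]) -> PeptideCatalogue:
    """A catalogue containing exactly the planted (peptide, activity) pairs."""
    entries = [CatalogueEntry(peptide=p, activity=a, entry_id=f"PL{i:03d}",
                              reference="planted")
               for i, (p, a) in enumerate(planted, start=1)]
    return PeptideCatalogue(entries)
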