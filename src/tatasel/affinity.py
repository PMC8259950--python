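"""TBP-promoter binding-affinity scoring.

The model treats TBP recognition of a core promoter as three coupled steps —
one-dimensional sliding along the DNA, retardation at a TATA/TBP-site, and
fixation of the complex by bending the double helix — and collapses them into
a single additive score per 15-bp window on the -ln(K_D) scale::

    S = w0 + w_pwm * PWM(window)
           + w_ta   * mean(ta_richness)
           + w_mg   * mean(minor_groove_width)
           + w_melt * mean(melting)

where ``PWM`` is the log-frequency position-weight-matrix score of the
window, the dinucleotide means run over the L-1 steps of the window, ``w0``
absorbs non-specific TBP-DNA affinity, and the remaining weights couple the
structural context (TA-richness, minor-groove geometry, local meltability)
that retards sliding TBP and stabilises the bent complex.

A promoter's affinity estimate is the maximum window score over a sliding
scan of both strands, reported with a standard error derived from the
spread of the top-scoring windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical TATA consensus planted by the synthetic generator (TATAWAWR
#: realised with the most frequent base at each core position).
TATA_CONSENSUS = "TATAAAAG"


class AffinityInputError(ValueError):
    """Raised for sequences or windows that violate model preconditions."""


class PwmFormatError(ValueError):
    """Raised when a position-weight-matrix file cannot be parsed."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, context: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - set(BASES)
    if bad:
        raise AffinityInputError(
            f"{context} contains non-ACGT characters: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class PromoterSequence:
    """A core-promoter sequence anchored to its transcription start site.

    ``tss_offset`` is the offset of the base immediately 5' of the TSS; the
    canonical 70-bp proximal promoter spans offsets -70..-1 with
    ``tss_offset = -1``.
    """

    gene_symbol: str
    sequence: str
    tss_offset: int = -1
    strand_label: str = "sense"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_alphabet(self.sequence,
                                                             "promoter"))

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_to_index(self, offset: int) -> int:
        """Map a TSS-relative offset (e.g. -30) to a 0-based string index."""
        idx = offset - (self.tss_offset - len(self.sequence) + 1)
        if not 0 <= idx < len(self.sequence):
            raise AffinityInputError(
                f"offset {offset} outside promoter window of {self.gene_symbol}"
            )
        return idx

    def index_to_offset(self, index: int) -> int:
        return index + (self.tss_offset - len(self.sequence) + 1)


@dataclass(frozen=True)
class TbpPwm:
    """Log-frequency position-weight matrix for the TBP-site."""

    weights: np.ndarray  # L x 4, natural-log frequencies
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 4:
            raise PwmFormatError(f"PWM must be Lx4 with L >= 4, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise PwmFormatError("PWM weights must be finite")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-9:
            raise PwmFormatError("background must be 4 positive freqs summing to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def score(self, window: str) -> float:
        """Sum of log-frequency weights over the window."""
        idx = [_BASE_INDEX[b] for b in window]
        return float(self.weights[np.arange(len(window)), idx].sum())


@dataclass(frozen=True)
class DinucScale:
    """A named map from the 16 dinucleotides to a physical property value."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = {a + b for a in BASES for b in BASES} - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing dinucleotides "
                             f"{sorted(missing)}")
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name} has non-finite values")

    def mean_over(self, window: str) -> float:
        vals = self.values
        return sum(vals[window[i:i + 2]]
                   for i in range(len(window) - 1)) / (len(window) - 1)


@dataclass(frozen=True)
class AffinityModelParams:
    """Weights and scan settings of the affinity model."""

    w0: float = 29.0
    w_pwm: float = 1.0
    w_ta: float = 0.2
    w_mg: float = -0.1
    w_melt: float = 0.1
    L: int = 15
    scan_both_strands: bool = True
    top_k_for_se: int = 10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.L < 4:
            raise ValueError("window length L must be >= 4")
        if self.top_k_for_se < 2:
            raise ValueError("top_k_for_se must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class AffinityEstimate:
    """-ln(K_D) +/- its standard error, with the best-site location.

    ``best_offset`` is the TSS-relative offset of the 5'-most base of the
    best window on the sense coordinates; ``best_strand`` is '+' or '-'.
    """

    value: float
    stderr: float
    best_offset: int
    best_strand: str


def load_pwm(path: str | Path, pseudocount: float = 0.5) -> TbpPwm:
    """Load a PWM from a TSV of L rows x 4 columns (A C G T) of counts.

    Counts (or frequencies) are converted to log frequencies after adding
    ``pseudocount`` to every cell. Lines starting with '#' and an optional
    'A C G T' header line are skipped.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if [f.strip().upper() for f in fields] == list(BASES):
                continue  # header
            if len(fields) != 4:
                raise PwmFormatError(
                    f"{path}: row at line {lineno} has {len(fields)} columns, "
                    "expected 4 (A C G T)")
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise PwmFormatError(
                    f"{path}: non-numeric cell at line {lineno}") from exc
    if len(rows) < 4:
        raise PwmFormatError(f"{path}: PWM has {len(rows)} rows, need >= 4")
    counts = np.asarray(rows, dtype=float) + pseudocount
    if np.any(counts <= 0):
        raise PwmFormatError(f"{path}: negative counts after pseudocount")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return TbpPwm(weights=np.log(freqs))


def load_scales(path: str | Path) -> dict[str, DinucScale]:
    """Load dinucleotide scales from a TSV (first column dinuc, one column
    per scale)."""
    header: list[str] | None = None
    columns: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for name in header[1:]:
                    columns[name] = {}
                continue
            dinuc = fields[0].upper()
            for name, cell in zip(header[1:], fields[1:]):
                columns[name][dinuc] = float(cell)
    return {name: DinucScale(name, vals) for name, vals in columns.items()}


def _data_path(name: str):
    return resources.files("tatasel.data").joinpath(name)


def default_pwm() -> TbpPwm:
    """The packaged TATA-box matrix."""
    with resources.as_file(_data_path("tbp_pwm.tsv")) as p:
        return load_pwm(p)


def default_scales() -> dict[str, DinucScale]:
    with resources.as_file(_data_path("dinuc_scales.tsv")) as p:
        return load_scales(p)


def default_params(**overrides) -> AffinityModelParams:
    with resources.as_file(_data_path("model_params.yaml")) as p:
        raw = yaml.safe_load(p.read_text())
    raw.pop("version", None)
    raw.update(overrides)
    return AffinityModelParams(**raw)


def window_score(window: str, pwm: TbpPwm,
                 scales: Mapping[str, DinucScale],
                 params: AffinityModelParams,
                 explain: bool = False):
    """Score a single L-length window; optionally return the term breakdown."""
    window = _check_alphabet(window, "window")
    if len(window) != params.L:
        raise AffinityInputError(
            f"window length {len(window)} != model L {params.L}")
    terms = {
        "w0": params.w0,
        "pwm": params.w_pwm * pwm.score(window),
        "ta": params.w_ta * scales["ta_richness"].mean_over(window),
        "mg": params.w_mg * scales["minor_groove_width"].mean_over(window),
        "melt": params.w_melt * scales["melting"].mean_over(window),
    }
    total = sum(terms.values())
    if explain:
        return total, terms
    return total


def _scan_scores(sequence: str, pwm, scales, params) -> list[tuple[float, int, str]]:
    """All (score, sense_offset_index, strand) triples for a sequence."""
    L = params.L
    out = []
    for i in range(len(sequence) - L + 1):
        out.append((window_score(sequence[i:i + L], pwm, scales, params),
                    i, "+"))
    if params.scan_both_strands:
        rc = reverse_complement(sequence)
        n = len(sequence)
        for i in range(n - L + 1):
            # window i..i+L-1 on rc covers sense indices n-L-i..n-1-i
            out.append((window_score(rc[i:i + L], pwm, scales, params),
                        n - L - i, "-"))
    return out


def estimate_affinity(seq: PromoterSequence, pwm: TbpPwm,
                      scales: Mapping[str, DinucScale],
                      params: AffinityModelParams) -> AffinityEstimate:
    """Scan every window of the promoter and return the affinity estimate.

    The value is the maximum window score; the standard error is the sample
    standard error of the ``top_k_for_se`` highest window scores. Ties for
    the maximum resolve to the sense strand first, then the smallest
    (most 5') offset.
    """
    if len(seq) < params.L:
        raise AffinityInputError(
            f"promoter {seq.gene_symbol} shorter ({len(seq)}) than window "
            f"L={params.L}")
    scored = _scan_scores(seq.sequence, pwm, scales, params)
    # deterministic tie-break: highest score, then '+' before '-', then 5'-most
    best = max(scored, key=lambda t: (t[0], t[2] == "+", -t[1]))
    scores = sorted((t[0] for t in scored), reverse=True)
    k = min(params.top_k_for_se, len(scores))
    top = np.asarray(scores[:k])
    stderr = float(top.std(ddof=1) / math.sqrt(k)) if k >= 2 else 0.0
    return AffinityEstimate(
        value=best[0],
        stderr=stderr,
        best_offset=seq.index_to_offset(best[1]),
        best_strand=best[2],
    )


def load_model(pwm_path=None, scales_path=None, params_path=None,
               **param_overrides):
    """Convenience loader returning (pwm, scales, params), defaulting to the
    packaged files."""
    pwm = load_pwm(pwm_path) if pwm_path else default_pwm()
    scales = load_scales(scales_path) if scales_path else default_scales()
    if params_path:
        raw = yaml.safe_load(Path(params_path).read_text())
        raw.pop("version", None)
        raw.update(param_overrides)
        params = AffinityModelParams(**raw)
    else:
        params = default_params(**param_overrides)
    return pwm, scales, params
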