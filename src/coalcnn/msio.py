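"""Reading and writing ms-style coalescent simulator output.

The ms output dialect (shared by ms, msmove and discoal) stores each
replicate as a ``//`` block followed by a ``segsites:`` line, a
``positions:`` line with site coordinates scaled to [0, 1], and one
0/1 string per sampled chromosome (0 = ancestral allele, 1 = derived).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypeAlignment",
    "MsParseError",
    "UnsupportedAlleleError",
    "read_ms",
    "write_ms",
]


class MsParseError(ValueError):
    """Malformed ms-style input (ragged rows, missing headers, ...)."""


class UnsupportedAlleleError(MsParseError):
    """Haplotype rows contain characters other than 0/1 (e.g. multiallelic codes)."""


@dataclass
class HaplotypeAlignment:
    """A raw simulated sample: binary allele matrix plus site positions.

    ``alleles`` has one row per sampled chromosome and one column per
    segregating site; entries are 0 (ancestral) or 1 (derived).
    ``positions`` are the site coordinates on [0, 1], nondecreasing, where
    1 corresponds to ``locus_length_bp`` physical base pairs.
    """

    alleles: np.ndarray
    positions: np.ndarray
    locus_length_bp: int = 1
    scenario_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            self.alleles = self.alleles.reshape(self.alleles.shape[0], -1)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError(
                f"positions has length {self.positions.size}, expected "
                f"{self.alleles.shape[1]} (one per segregating site)"
            )
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise UnsupportedAlleleError("allele matrix entries must be 0 or 1")
        if self.positions.size:
            if self.positions.min() < 0 or self.positions.max() > 1:
                raise ValueError("positions must lie in [0, 1]")
            if np.any(np.diff(self.positions) < 0):
                raise ValueError("positions must be nondecreasing")

    @property
    def n_chroms(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


def _as_lines(stream) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    if isinstance(stream, (bytes, bytearray)):
        return stream.decode().splitlines()
    return stream.read().splitlines() if isinstance(stream, io.IOBase) else list(stream)


def read_ms(stream, locus_length_bp: int = 1) -> list[HaplotypeAlignment]:
    """Parse ms-style output into one :class:`HaplotypeAlignment` per replicate.

    Replicates are returned in file order; chromosome order within a
    replicate is preserved. A ``segsites: 0`` replicate yields an empty
    matrix. Raises :class:`MsParseError` for ragged haplotype rows and
    :class:`UnsupportedAlleleError` for non-0/1 allele codes.
    """
    lines = _as_lines(stream)
    # locate replicate delimiters; everything before the first // is header
    starts = [i for i, ln in enumerate(lines) if ln.strip() == "//"]
    alignments: list[HaplotypeAlignment] = []
    n_chroms_expected: int | None = None
    # an "ms nsam nreps ..." command line fixes the sample size, which is
    # otherwise unknowable for zero-segsite replicates
    for ln in lines[: starts[0]] if starts else []:
        parts = ln.split()
        if len(parts) >= 3 and parts[0].endswith("ms") and parts[1].isdigit():
            n = int(parts[1])
            if n > 0:
                n_chroms_expected = n
            break
    for rep_idx, start in enumerate(starts):
        end = starts[rep_idx + 1] if rep_idx + 1 < len(starts) else len(lines)
        block = [ln.strip() for ln in lines[start + 1 : end]]
        seg_line = next((ln for ln in block if ln.startswith("segsites:")), None)
        if seg_line is None:
            raise MsParseError(f"replicate {rep_idx}: missing 'segsites:' line")
        n_sites = int(seg_line.split(":", 1)[1])
        if n_sites == 0:
            # sample size is unknowable from an empty block unless already seen
            n = n_chroms_expected or 0
            alignments.append(
                HaplotypeAlignment(
                    np.zeros((n, 0), dtype=np.int8),
                    np.zeros(0),
                    locus_length_bp=locus_length_bp,
                    scenario_id=f"rep{rep_idx}",
                )
            )
            continue
        pos_line = next((ln for ln in block if ln.startswith("positions:")), None)
        if pos_line is None:
            raise MsParseError(f"replicate {rep_idx}: missing 'positions:' line")
        positions = np.array([float(p) for p in pos_line.split(":", 1)[1].split()])
        if positions.size != n_sites:
            raise MsParseError(
                f"replicate {rep_idx}: {positions.size} positions for {n_sites} segsites"
            )
        pos_at = block.index(pos_line)
        rows = []
        for ln in block[pos_at + 1 :]:
            if not ln:
                if rows:
                    break
                continue
            if ln.startswith(("segsites:", "positions:", "prob:")) or ln == "//":
                break
            if set(ln) - {"0", "1"}:
                bad = sorted(set(ln) - {"0", "1"})
                raise UnsupportedAlleleError(
                    f"replicate {rep_idx}: unsupported allele codes {bad}; "
                    "only biallelic 0/1 data are supported"
                )
            if len(ln) != n_sites:
                raise MsParseError(
                    f"replicate {rep_idx}: haplotype row of length {len(ln)}, "
                    f"expected {n_sites}"
                )
            rows.append(np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0"))
        if not rows:
            raise MsParseError(f"replicate {rep_idx}: no haplotype rows")
        if n_chroms_expected is None:
            n_chroms_expected = len(rows)
        elif len(rows) != n_chroms_expected:
            raise MsParseError(
                f"replicate {rep_idx}: {len(rows)} chromosomes, expected "
                f"{n_chroms_expected} (sample size must be constant)"
            )
        alignments.append(
            HaplotypeAlignment(
                np.vstack(rows).astype(np.int8),
                positions,
                locus_length_bp=locus_length_bp,
                scenario_id=f"rep{rep_idx}",
            )
        )
    return alignments


def write_ms(alignments: list[HaplotypeAlignment], decimals: int = 6) -> str:
    """Serialize alignments to ms-dialect text.

    Positions are printed with ``decimals`` decimal places (6 by default,
    matching common ms builds), so ``read_ms(write_ms(x))`` reproduces
    allele matrices exactly and positions to printed precision. All
    alignments must share the same sample size.
    """
    sizes = {a.n_chroms for a in alignments}
    if len(sizes) > 1:
        raise ValueError(f"mixed sample sizes {sorted(sizes)}; write_ms requires one")
    n = sizes.pop() if sizes else 0
    out = [f"ms {n} {len(alignments)}", "0 0 0", ""]
    for aln in alignments:
        out.append("//")
        out.append(f"segsites: {aln.n_sites}")
        if aln.n_sites:
            out.append(
                "positions: " + " ".join(f"{p:.{decimals}f}" for p in aln.positions)
            )
            for row in aln.alleles:
                out.append("".join("1" if v else "0" for v in row))
        out.append("")
    return "\n".join(out)
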