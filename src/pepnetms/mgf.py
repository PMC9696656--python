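"""Strict MGF (Mascot generic format) reading and writing.

Dialect: one ``BEGIN IONS``/``END IONS`` block per spectrum; ``TITLE``
carries the spectrum id; ``PEPMASS`` the precursor m/z; ``CHARGE`` is
written ``1+`` (``+1``, ``1`` and ``1-`` are accepted on input);
``RTINSECONDS`` is optional.  Peak lines are ``m/z intensity``.  Malformed
input raises :class:`MGFError` with the offending line number.
"""

from __future__ import annotations

import io
import os
import re
from typing import Iterable

from .spectrum import Peak, Spectrum

__all__ = ["MGFError", "read_mgf", "write_mgf"]


class MGFError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


_CHARGE = re.compile(r"^([+-]?)(\d+)([+-]?)$")


def _parse_charge(text: str, lineno: int) -> int:
    m = _CHARGE.match(text.strip())
    if not m or (m.group(1) and m.group(3)):
        raise MGFError(f"unparsable CHARGE value {text!r}", lineno)
    sign = -1 if "-" in (m.group(1), m.group(3)) else 1
    return sign * int(m.group(2))


def read_mgf(source) -> list[Spectrum]:
    """Read spectra from a path, file object or MGF text."""
    if isinstance(source, str) and (
        "\n" in source or source.lstrip().startswith("BEGIN IONS") or not source.strip()
    ):
        lines = source.splitlines()
    elif isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, io.IOBase):
        lines = source.read().splitlines()
    else:
        lines = list(source)

    spectra: list[Spectrum] = []
    in_block = False
    block_start = 0
    headers: dict[str, str] = {}
    peaks: list[Peak] = []
    counter = 0

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                raise MGFError("nested BEGIN IONS", lineno)
            in_block, block_start = True, lineno
            headers, peaks = {}, []
        elif line == "END IONS":
            if not in_block:
                raise MGFError("END IONS without BEGIN IONS", lineno)
            in_block = False
            counter += 1
            if "PEPMASS" not in headers:
                raise MGFError("block missing PEPMASS", lineno)
            try:
                pepmass = float(headers["PEPMASS"].split()[0])
            except ValueError:
                raise MGFError(
                    f"non-numeric PEPMASS {headers['PEPMASS']!r}", lineno
                ) from None
            charge = (
                _parse_charge(headers["CHARGE"], lineno)
                if "CHARGE" in headers
                else 1
            )
            rt = float(headers["RTINSECONDS"]) if "RTINSECONDS" in headers else None
            spectra.append(
                Spectrum(
                    id=headers.get("TITLE", f"spectrum_{counter}"),
                    precursor_mz=pepmass,
                    precursor_charge=abs(charge),
                    retention_time=rt,
                    peaks=tuple(peaks),
                )
            )
        elif in_block:
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                headers[key.strip().upper()] = value.strip()
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise MGFError(f"malformed peak line {line!r}", lineno)
                try:
                    peaks.append(Peak(float(fields[0]), float(fields[1])))
                except ValueError:
                    raise MGFError(
                        f"non-numeric peak line {line!r}", lineno
                    ) from None
        else:
            raise MGFError(f"content outside BEGIN IONS block: {line!r}", lineno)

    if in_block:
        raise MGFError("missing END IONS", block_start)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], destination) -> None:
    """Write spectra to a path or file object (m/z and intensities to six
    decimals; reading back preserves values at that precision)."""

    def _dump(fh):
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            sign = "+" if s.precursor_charge >= 0 else "-"
            fh.write(f"CHARGE={abs(s.precursor_charge)}{sign}\n")
            if s.retention_time is not None:
                fh.write(f"RTINSECONDS={s.retention_time:.3f}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("END IONS\n")

    if isinstance(destination, (str, os.PathLike)):
        with open(destination, "w") as fh:
            _dump(fh)
    else:
        _dump(destination)
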