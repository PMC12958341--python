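"""Minimal JCAMP-DX reader/writer for 1D NMR spectra.

Implements the fixed-form AFFN ``XYDATA=(X++(Y..Y))`` dialect: enough to
round-trip this package's own output and to read simple exports from other
software.  Compressed (SQZ/DIF/DUP) ordinates are out of scope.
"""

from __future__ import annotations

import warnings

import numpy as np

from .processing import FormatError, Spectrum

__all__ = ["read_jcamp", "write_jcamp"]


def write_jcamp(spec: Spectrum, path, title: str = "rcfqnmr spectrum") -> None:
    n = spec.ppm.size
    # store in descending ppm order, as held in memory
    firstx, lastx = float(spec.ppm[0]), float(spec.ppm[-1])
    ymax = float(np.max(np.abs(spec.intensity))) or 1.0
    yfactor = ymax / 1e9  # keep ordinates within ~9 significant digits
    with open(path, "w") as fh:
        fh.write(f"##TITLE={title}\n")
        fh.write("##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##XUNITS=PPM\n")
        fh.write("##YUNITS=ARBITRARY UNITS\n")
        if spec.sf_mhz is not None:
            fh.write(f"##.OBSERVE FREQUENCY={spec.sf_mhz:.6f}\n")
        fh.write("##.OBSERVE NUCLEUS=^1H\n")
        fh.write(f"##NPOINTS={n}\n")
        fh.write(f"##FIRSTX={firstx:.10g}\n")
        fh.write(f"##LASTX={lastx:.10g}\n")
        fh.write("##XFACTOR=1.0\n")
        fh.write(f"##YFACTOR={yfactor:.10g}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        per_line = 6
        y = spec.intensity / yfactor
        for i in range(0, n, per_line):
            chunk = y[i : i + per_line]
            fh.write(f"{spec.ppm[i]:.8g} " + " ".join(f"{v:.10g}" for v in chunk) + "\n")
        fh.write("##END=\n")


def read_jcamp(path) -> Spectrum:
    meta: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    firstx = lastx = None
    npoints = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if "=" not in line:
                    raise FormatError(f"{path}: line {lineno}: malformed label {line!r}")
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                val = val.strip()
                if key == "XYDATA":
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                    continue
                meta[key] = val
                continue
            if not in_data:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected X then Y values")
            try:
                ys.extend(float(p) for p in parts[1:])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    try:
        firstx = float(meta["FIRSTX"])
        lastx = float(meta["LASTX"])
        npoints = int(float(meta["NPOINTS"]))
    except KeyError as exc:
        raise FormatError(f"{path}: missing required JCAMP label {exc}") from exc
    if len(ys) != npoints:
        raise FormatError(f"{path}: NPOINTS={npoints} but {len(ys)} ordinates found")
    yfactor = float(meta.get("YFACTOR", 1.0))
    xfactor = float(meta.get("XFACTOR", 1.0))
    ppm = np.linspace(firstx, lastx, npoints) * xfactor
    intensity = np.asarray(ys) * yfactor
    sf = None
    if ".OBSERVE FREQUENCY" in meta:
        sf = float(meta[".OBSERVE FREQUENCY"])
    else:
        warnings.warn(f"{path}: no spectrometer frequency metadata; sf_mhz unset")
    return Spectrum(ppm, intensity, sf_mhz=sf, provenance={"source": str(path), "format": "jcamp"})
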