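"""Curve and report I/O.

Scattering curves use the whitespace-delimited 3-column (q, I, σ) text
dialect with '#'-prefixed header lines; 2-column files are accepted as
theoretical curves without errors.  Units at the boundary: q in Å⁻¹,
lengths in Å, b in fm, SLD in Å⁻².
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .scattering import ScatteringCurve


def read_curve(path: str | Path, radiation: str = "xray") -> ScatteringCurve:
    """Read a (q, I[, σ]) text file; '#' headers and blank lines ignored."""
    path = Path(path)
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed line {stripped!r}") from None
            if len(vals) < 2:
                raise ValueError(f"{path}:{lineno}: fewer than 2 columns")
            if ncols is None:
                ncols = min(len(vals), 3)
            rows.append(vals[:ncols])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    if sigma is not None and np.any(sigma <= 0):
        raise ValueError(f"{path}: non-positive sigma values present")
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma, radiation,
                           {"source": str(path)})


def write_curve(curve: ScatteringCurve, path: str | Path,
                header: str | None = None) -> None:
    path = Path(path)
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    lines.append("#        q              I          sigma"
                 if curve.sigma is not None else "#        q              I")
    for i in range(len(curve)):
        if curve.sigma is not None:
            lines.append(f"{curve.q[i]:15.8e} {curve.I[i]:15.8e} "
                         f"{curve.sigma[i]:15.8e}")
        else:
            lines.append(f"{curve.q[i]:15.8e} {curve.I[i]:15.8e}")
    path.write_text("\n".join(lines) + "\n")


def write_pr_report(pr, path: str | Path) -> None:
    """GNOM-style plain-text block: q/I_exp/I_fit table then r/P(r) table,
    plus a machine-readable JSON sidecar."""
    path = Path(path)
    lines = ["# indirect Fourier transform result",
             f"# Dmax = {pr.dmax:.2f} A   alpha = {pr.alpha:.6g}   "
             f"chi2 = {pr.chi2:.4f}", "#", "#        q          I_fit"]
    for i in range(len(pr.i_fit)):
        lines.append(f"{pr.i_fit.q[i]:13.6e} {pr.i_fit.I[i]:13.6e}")
    lines += ["#", "#        r           P(r)"]
    for i in range(len(pr.r)):
        lines.append(f"{pr.r[i]:13.6e} {pr.p[i]:13.6e}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {"dmax": pr.dmax, "alpha": pr.alpha, "chi2": pr.chi2,
               "r": pr.r.tolist(), "p": pr.p.tolist()}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items()
                    if not k.startswith("_")}
        return str(o)
    Path(path).write_text(json.dumps(obj, indent=1, default=default))
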