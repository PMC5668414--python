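"""Extended-XYZ trajectory I/O.

Dialect: per frame, a bead-count line; a comment line with space-separated
``key=value`` tokens carrying at least ``box_length``; then one line per
bead with columns ``species x y z charge radius chain`` (chain is the
0-based chain index or -1 for free ions).  Positions are printed with 10
significant digits, so write-then-read is the identity to printed
precision.
"""

from __future__ import annotations

import numpy as np

from .mc import Trajectory
from .model import SPECIES, SPECIES_CODE, Configuration

__all__ = ["write_trajectory", "read_trajectory", "write_configuration"]


def _frame_lines(config: Configuration, positions: np.ndarray, comment: str):
    yield f"{config.n_beads}\n"
    yield comment + "\n"
    _, _, bead_chain = config.chain_arrays()
    for i in range(config.n_beads):
        yield (
            f"{SPECIES[config.species[i]]} "
            f"{positions[i, 0]:.10g} {positions[i, 1]:.10g} {positions[i, 2]:.10g} "
            f"{config.charges[i]:.10g} {config.radii[i]:.10g} {bead_chain[i]}\n"
        )


def write_configuration(config: Configuration, path, **extra) -> None:
    write_trajectory(
        Trajectory(
            template=config,
            frames=config.positions[None, :, :],
            energies=np.zeros(1),
            metadata={},
        ),
        path,
        **extra,
    )


def write_trajectory(trajectory: Trajectory, path, **extra) -> None:
    tmpl = trajectory.template
    base = {"box_length": f"{tmpl.box_length:.10g}"}
    base.update({k: str(v) for k, v in extra.items()})
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            tokens = dict(base)
            tokens["frame"] = str(f)
            tokens["energy"] = f"{trajectory.energies[f]:.10g}"
            comment = " ".join(f"{k}={v}" for k, v in tokens.items())
            fh.writelines(_frame_lines(tmpl, trajectory.frames[f], comment))


class TrajectoryParseError(ValueError):
    pass


def read_trajectory(path) -> Trajectory:
    """Read the dialect written by :func:`write_trajectory`.

    Raises with the offending line number on malformed headers, and names
    the last complete frame when the file is truncated mid-frame.
    """
    with open(path) as fh:
        lines = fh.readlines()
    frames = []
    energies = []
    template = None
    ln = 0
    nframe = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nbeads = int(lines[ln].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"line {ln + 1}: expected a bead count, got {lines[ln]!r}"
            )
        if ln + 1 >= len(lines):
            raise TrajectoryParseError(
                f"truncated file after frame {nframe - 1} (missing comment line "
                f"at line {ln + 2})"
            )
        tokens = {}
        for tok in lines[ln + 1].split():
            if "=" not in tok:
                raise TrajectoryParseError(
                    f"line {ln + 2}: malformed comment token {tok!r}"
                )
            k, v = tok.split("=", 1)
            tokens[k] = v
        if "box_length" not in tokens:
            raise TrajectoryParseError(f"line {ln + 2}: comment lacks box_length")
        if ln + 2 + nbeads > len(lines):
            raise TrajectoryParseError(
                f"truncated file: frame {nframe} incomplete; last good frame is "
                f"{nframe - 1}"
            )
        pos = np.empty((nbeads, 3))
        species = np.empty(nbeads, dtype=np.int64)
        charges = np.empty(nbeads)
        radii = np.empty(nbeads)
        chain_ids = np.empty(nbeads, dtype=np.int64)
        for b in range(nbeads):
            parts = lines[ln + 2 + b].split()
            if len(parts) != 7:
                raise TrajectoryParseError(
                    f"line {ln + 3 + b}: expected 7 columns, got {len(parts)}"
                )
            if parts[0] not in SPECIES_CODE:
                raise TrajectoryParseError(
                    f"line {ln + 3 + b}: unknown species label {parts[0]!r}"
                )
            species[b] = SPECIES_CODE[parts[0]]
            pos[b] = [float(parts[1]), float(parts[2]), float(parts[3])]
            charges[b] = float(parts[4])
            radii[b] = float(parts[5])
            chain_ids[b] = int(parts[6])
        if template is None:
            chains = []
            b = 0
            while b < nbeads:
                if chain_ids[b] >= 0:
                    start = b
                    cid = chain_ids[b]
                    while b < nbeads and chain_ids[b] == cid:
                        b += 1
                    chains.append((start, b - start))
                else:
                    b += 1
            template = Configuration(
                positions=pos,
                species=species,
                radii=radii,
                charges=charges,
                chains=tuple(chains),
                box_length=float(tokens["box_length"]),
            )
        frames.append(pos)
        energies.append(float(tokens.get("energy", "nan")))
        ln += 2 + nbeads
        nframe += 1
    if template is None:
        raise TrajectoryParseError("file contains no frames")
    return Trajectory(
        template=template,
        frames=np.stack(frames),
        energies=np.array(energies),
        metadata={"source": str(path)},
    )
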