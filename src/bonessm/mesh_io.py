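"""ASCII PLY serialization for point clouds with per-point normals.

trimesh handles triangulated surfaces, but its point-cloud export does not
round-trip normals, so clouds use this minimal ASCII PLY writer/reader
(properties x y z nx ny nz, plus a comment carrying the recorded centroid size).
"""

from __future__ import annotations

import numpy as np

from .mesh import PointCloud

__all__ = ["write_point_cloud", "read_point_cloud"]


def write_point_cloud(cloud: PointCloud, path) -> None:
    n = len(cloud)
    has_normals = cloud.normals is not None
    lines = ["ply", "format ascii 1.0"]
    if cloud.centroid_size is not None:
        lines.append(f"comment centroid_size {cloud.centroid_size!r}")
    if cloud.instance_id:
        lines.append(f"comment instance_id {cloud.instance_id}")
    lines.append(f"element vertex {n}")
    lines += [f"property double {p}" for p in ("x", "y", "z")]
    if has_normals:
        lines += [f"property double {p}" for p in ("nx", "ny", "nz")]
    lines.append("end_header")
    data = cloud.points if not has_normals else np.hstack([cloud.points, cloud.normals])
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in data)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n" + body + "\n")


def read_point_cloud(path) -> PointCloud:
    with open(path) as fh:
        text = fh.read().splitlines()
    if not text or text[0].strip() != "ply":
        raise IOError(f"{path}: not a PLY file")
    centroid_size = None
    instance_id = ""
    n = None
    props: list[str] = []
    i = 0
    for i, line in enumerate(text[1:], start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "comment" and len(tok) >= 3 and tok[1] == "centroid_size":
            centroid_size = float(tok[2])
        elif tok[0] == "comment" and len(tok) >= 3 and tok[1] == "instance_id":
            instance_id = tok[2]
        elif tok[0] == "element" and tok[1] == "vertex":
            n = int(tok[2])
        elif tok[0] == "property":
            props.append(tok[-1])
        elif tok[0] == "end_header":
            break
    if n is None:
        raise IOError(f"{path}: malformed PLY header")
    rows = [list(map(float, ln.split())) for ln in text[i + 1 : i + 1 + n]]
    if len(rows) != n:
        raise IOError(f"{path}: expected {n} points, found {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    points = arr[:, :3]
    normals = arr[:, 3:6] if "nx" in props and arr.shape[1] >= 6 else None
    return PointCloud(
        points=points, normals=normals, centroid_size=centroid_size,
        instance_id=instance_id,
    )
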