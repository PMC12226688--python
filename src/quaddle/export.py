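"""3D file export: Wavefront OBJ+MTL and glTF 2.0 with embedded textures.

Both writers are pure text/JSON emitters so that identical inputs produce
byte-identical files.  The in-package convention is +z up with +y toward the
viewer; glTF output converts to the format's +y-up convention
((x, y, z) -> (x, z, -y)).  OBJ carries no axis convention and is written
in model axes.
"""

from __future__ import annotations

import base64
import hashlib
import io
import json
from pathlib import Path

import numpy as np

from .geometry import TriMesh
from .textures import TextureImage


def object_identifier(index: int, spec_row: str) -> str:
    """Zero-padded index plus an 8-hex digest of the spec row."""
    digest = hashlib.sha256(spec_row.encode("utf-8")).hexdigest()[:8]
    return f"{index:03d}-{digest}"


def _require_uvs(mesh: TriMesh) -> None:
    if mesh.uvs is None:
        raise ValueError("mesh has no UVs; run planar_uv before exporting")


def _part_submeshes(mesh: TriMesh) -> list[tuple[str, np.ndarray, np.ndarray, np.ndarray]]:
    """Split by part label into (label, vertices, uvs, reindexed faces)."""
    out = []
    for label in dict.fromkeys(mesh.part_labels):  # stable order of appearance
        fsel = mesh.faces[mesh.part_labels == label]
        used, inverse = np.unique(fsel.ravel(), return_inverse=True)
        out.append((str(label), mesh.vertices[used], mesh.uvs[used],
                    inverse.reshape(fsel.shape).astype(np.int64)))
    return out


def export_obj(mesh: TriMesh, textures: dict, base_path) -> list[Path]:
    """Write <base>.obj, <base>.mtl, and per-part texture PNGs.

    Faces are grouped per part with one material each; materials with a
    :class:`TextureImage` reference their PNG through ``map_Kd``, plain-color
    parts use a diffuse ``Kd``.  Re-parsing reproduces the vertex and face
    counts exactly.
    """
    _require_uvs(mesh)
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    obj_path = base.with_suffix(".obj")
    mtl_path = base.with_suffix(".mtl")
    written = [obj_path, mtl_path]

    obj = io.StringIO()
    mtl = io.StringIO()
    obj.write(f"mtllib {mtl_path.name}\n")
    offset = 1  # OBJ indices are 1-based
    for label, verts, uvs, faces in _part_submeshes(mesh):
        mat = f"{label}_mat"
        mtl.write(f"newmtl {mat}\n")
        tex = textures.get(label)
        if isinstance(tex, TextureImage):
            tex_path = base.parent / f"{base.name}_{label}.png"
            tex.save(tex_path)
            written.append(tex_path)
            mtl.write("Kd 1.000000 1.000000 1.000000\n")
            mtl.write(f"map_Kd {tex_path.name}\n")
        else:
            rgb = tuple(int(c) for c in (tex or (255, 255, 255)))
            mtl.write("Kd {:.6f} {:.6f} {:.6f}\n".format(*(c / 255.0 for c in rgb)))
        obj.write(f"g {label}\nusemtl {mat}\n")
        for v in verts:
            obj.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for uv in uvs:
            obj.write(f"vt {uv[0]:.9g} {uv[1]:.9g}\n")
        for f in faces:
            ids = [offset + int(i) for i in f]
            obj.write("f {0}/{0} {1}/{1} {2}/{2}\n".format(*ids))
        offset += len(verts)
    obj_path.write_text(obj.getvalue(), encoding="utf-8")
    mtl_path.write_text(mtl.getvalue(), encoding="utf-8")
    return written


def _to_y_up(vertices: np.ndarray) -> np.ndarray:
    return np.column_stack([vertices[:, 0], vertices[:, 2], -vertices[:, 1]])


def _png_bytes(tex: TextureImage) -> bytes:
    buf = io.BytesIO()
    tex.to_pil().save(buf, format="PNG")
    return buf.getvalue()


def export_gltf(mesh: TriMesh, textures: dict, path) -> Path:
    """Write a self-contained glTF 2.0 asset (JSON with data-URI buffers).

    One primitive per part with POSITION/TEXCOORD_0 accessors (min/max set
    from the data), embedded PNG textures, and +y-up axis conversion.
    """
    _require_uvs(mesh)
    path = Path(path).with_suffix(".gltf")
    path.parent.mkdir(parents=True, exist_ok=True)

    buffer = bytearray()
    buffer_views = []
    accessors = []
    images = []
    gltf_textures = []
    materials = []
    primitives = []
    samplers = [{"magFilter": 9729, "minFilter": 9729,
                 "wrapS": 10497, "wrapT": 10497}]

    def add_view(data: bytes, target: int | None = None) -> int:
        while len(buffer) % 4:
            buffer.append(0)
        view = {"buffer": 0, "byteOffset": len(buffer), "byteLength": len(data)}
        if target is not None:
            view["target"] = target
        buffer.extend(data)
        buffer_views.append(view)
        return len(buffer_views) - 1

    for label, verts, uvs, faces in _part_submeshes(mesh):
        pos = _to_y_up(verts).astype(np.float32)
        uv_gl = np.column_stack([uvs[:, 0], 1.0 - uvs[:, 1]]).astype(np.float32)
        idx = faces.reshape(-1).astype(np.uint32)

        vi = add_view(pos.tobytes(), target=34962)
        accessors.append({
            "bufferView": vi, "componentType": 5126, "count": len(pos),
            "type": "VEC3",
            "min": [float(x) for x in pos.min(axis=0)],
            "max": [float(x) for x in pos.max(axis=0)],
        })
        a_pos = len(accessors) - 1
        vi = add_view(uv_gl.tobytes(), target=34962)
        accessors.append({"bufferView": vi, "componentType": 5126,
                          "count": len(uv_gl), "type": "VEC2"})
        a_uv = len(accessors) - 1
        vi = add_view(idx.tobytes(), target=34963)
        accessors.append({"bufferView": vi, "componentType": 5125,
                          "count": len(idx), "type": "SCALAR"})
        a_idx = len(accessors) - 1

        tex = textures.get(label)
        material = {"name": f"{label}_mat", "doubleSided": True,
                    "pbrMetallicRoughness": {"metallicFactor": 0.0,
                                             "roughnessFactor": 1.0}}
        if isinstance(tex, TextureImage):
            png = _png_bytes(tex)
            images.append({
                "mimeType": "image/png",
                "uri": "data:image/png;base64," + base64.b64encode(png).decode("ascii"),
            })
            gltf_textures.append({"sampler": 0, "source": len(images) - 1})
            material["pbrMetallicRoughness"]["baseColorTexture"] = {
                "index": len(gltf_textures) - 1}
        else:
            rgb = tuple(int(c) for c in (tex or (255, 255, 255)))
            material["pbrMetallicRoughness"]["baseColorFactor"] = [
                rgb[0] / 255.0, rgb[1] / 255.0, rgb[2] / 255.0, 1.0]
        materials.append(material)
        primitives.append({
            "attributes": {"POSITION": a_pos, "TEXCOORD_0": a_uv},
            "indices": a_idx, "material": len(materials) - 1, "mode": 4,
        })

    uri = "data:application/octet-stream;base64," + \
        base64.b64encode(bytes(buffer)).decode("ascii")
    gltf = {
        "asset": {"version": "2.0", "generator": "quaddle"},
        "scene": 0,
        "scenes": [{"nodes": [0]}],
        "nodes": [{"mesh": 0}],
        "meshes": [{"primitives": primitives}],
        "materials": materials,
        "accessors": accessors,
        "bufferViews": buffer_views,
        "buffers": [{"byteLength": len(buffer), "uri": uri}],
        "samplers": samplers,
    }
    if images:
        gltf["images"] = images
        gltf["textures"] = gltf_textures
    else:
        del gltf["samplers"]
    path.write_text(json.dumps(gltf, indent=1), encoding="utf-8")
    return path
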