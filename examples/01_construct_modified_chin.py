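"""Construct the modified chin point for a single profile.

Builds a hand-specified midline profile (mm, sagittal coordinates with
subnasale at the origin), runs the 170-degree convexity construction,
and prints the actual vs modified chin point and their horizontal
offset x.  A negative x means the modified point lies posterior to the
actual chin, as in a prognathic (Class III) profile.
"""

from chinpoint import ProfilePoint, construct_chin, facial_convexity_angle

g = ProfilePoint(0.0, 80.0)  # soft-tissue glabella
sn = ProfilePoint(0.0, 0.0)  # subnasale (origin)
acp = ProfilePoint(5.0, -55.0)  # soft-tissue pogonion, 5 mm anterior

construction = construct_chin(g, sn, acp, target_angle=170.0)

print(f"facial convexity at ACP : {facial_convexity_angle(g, sn, acp):8.2f} deg")
print(f"ACP (a, s)              : ({construction.acp.a:7.2f}, {construction.acp.s:7.2f}) mm")
print(f"MCP (a, s)              : ({construction.mcp.a:7.2f}, {construction.mcp.s:7.2f}) mm")
print(f"horizontal offset x     : {construction.x:8.2f} mm (anterior-positive)")
print(f"ACP-to-MCP distance |x| : {abs(construction.x):8.2f} mm")
print(f"convexity at MCP        : {facial_convexity_angle(g, sn, construction.mcp):8.2f} deg")
print()
print(
    "The modified point realizes the 170-degree target exactly; the |x|\n"
    "value is the chin correction a surgeon would plan to standardize\n"
    "this profile's convexity."
)
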