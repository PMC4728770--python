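<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="744" height="110" viewBox="0 0 744 110">
<defs><pattern id="unmapped" width="6" height="6" patternUnits="userSpaceOnUse" patternTransform="rotate(45)"><rect width="6" height="6" fill="#ffffff"/><line x1="0" y1="0" x2="0" y2="6" stroke="#bbbbbb" stroke-width="2"/></pattern></defs>
<rect x="0" y="0" width="744" height="110" fill="#ffffff"/>
<rect x="12" y="46" width="12" height="18" fill="#008080"/>
<rect x="24" y="46" width="12" height="18" fill="#808080"/>
<rect x="36" y="46" width="12" height="18" fill="#ff8080"/>
<text x="12" y="24" font-family="DejaVu Sans Mono, monospace" font-size="12" text-anchor="start" fill="#000000">&gt;collinear_3_A (3 residues)</text>
<text x="18" y="60" font-family="DejaVu Sans Mono, monospace" font-size="12" text-anchor="middle" fill="#ffffff">A</text>
<text x="30" y="60" font-family="DejaVu Sans Mono, monospace" font-size="12" text-anchor="middle" fill="#000000">A</text>
<text x="42" y="60" font-family="DejaVu Sans Mono, monospace" font-size="12" text-anchor="middle" fill="#000000">A</text>
<text x="12" y="85" font-family="DejaVu Sans Mono, monospace" font-size="9" text-anchor="start" fill="#3c3c3c">mode=cb  s_max=23.00 A  centroid=(23.00, 0.00, 0.00)</text>
</svg>
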