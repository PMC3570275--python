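# Mammalian cell-cycle Boolean network, 10 nodes.
# Node order: 1 CycD, 2 Rb, 3 E2F, 4 CycE, 5 CycA, 6 p27, 7 CDC20, 8 CDH1, 9 UbcH10, 10 CycB
$node[1] = $node[1];
$node[2] = (!($node[1]) & !($node[4]) & !($node[5]) & !($node[10])) | ($node[6] & !($node[1]) & !($node[10]));
$node[3] = (!($node[2]) & !($node[5]) & !($node[10])) | ($node[6] & !($node[2]) & !($node[10]));
$node[4] = ($node[3] & !($node[2]));
$node[5] = ($node[3] & !($node[2]) & !($node[7]) & !($node[8] & $node[9])) | ($node[5] & !($node[2]) & !($node[7]) & !($node[8] & $node[9]));
$node[6] = (!($node[1]) & !($node[4]) & !($node[5]) & !($node[10])) |($node[6] & !($node[4] & $node[5]) & !($node[10]) & !($node[1]));
$node[7] = $node[10];
$node[8] = (!($node[5]) & !($node[10])) |$node[7] |($node[6] & !($node[10]));
$node[9] = !($node[8]) |($node[8] & $node[9] & ($node[7] | $node[5] | $node[10]));
$node[10] = (!($node[7]) & !($node[8]));
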