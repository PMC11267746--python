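Avenida Los Aromos 1420
Calle Las Encinas 236
Pasaje Los Canelos 18
Avenida Las Araucarias 3105
Calle Los Alerces 742
Pasaje Las Hortensias 55
Avenida Los Boldos 980
Calle Los Notros 1211
Pasaje Los Maitenes 7
Avenida Las Camelias 2460
Calle Los Lingues 333
Pasaje Las Violetas 91
Avenida Los Peumos 1544
Calle Las Magnolias 28
Pasaje Los Quillayes 130
Avenida Los Radales 615
Calle Las Azucenas 870
Pasaje Los Avellanos 44
Avenida Las Dalias 1930
Calle Los Coigües 507
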