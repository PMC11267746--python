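Región de Arica y Parinacota
Región de Tarapacá
Región de Antofagasta
Región de Atacama
Región de Coquimbo
Región de Valparaíso
Región Metropolitana
Región del Libertador General Bernardo O'Higgins
Región del Maule
Región de Ñuble
Región del Biobío
Región de La Araucanía
Región de Los Ríos
Región de Los Lagos
Región de Aysén
Región de Magallanes
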