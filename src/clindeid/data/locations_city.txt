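Santiago
Valparaíso
Concepción
Antofagasta
Temuco
Rancagua
Talca
Arica
Iquique
Calama
Copiapó
Coquimbo
Ovalle
Quillota
Melipilla
Curicó
Linares
Chillán
Los Ángeles
Angol
Villarrica
Osorno
Valdivia
Ancud
Castro
Coyhaique
Maipú
Puente Alto
La Florida
Ñuñoa
Providencia
Recoleta
Quilicura
Renca
Cerrillos
Pudahuel
Peñalolén
Macul
Buin
Paine
Lampa
Colina
Talagante
Graneros
Machalí
Rengo
Molina
Cauquenes
Parral
Collipulli
Lautaro
Loncoche
Frutillar
Llanquihue
Quellón
Porvenir
Tocopilla
Taltal
Vallenar
Illapel
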