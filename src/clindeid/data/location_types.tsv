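Región de Arica y Parinacota	region
Región de Tarapacá	region
Región de Antofagasta	region
Región de Atacama	region
Región de Coquimbo	region
Región de Valparaíso	region
Región Metropolitana	region
Región del Libertador General Bernardo O'Higgins	region
Región del Maule	region
Región de Ñuble	region
Región del Biobío	region
Región de La Araucanía	region
Región de Los Ríos	region
Región de Los Lagos	region
Región de Aysén	region
Región de Magallanes	region
Santiago	city
Valparaíso	city
Concepción	city
Antofagasta	city
Temuco	city
Rancagua	city
Talca	city
Arica	city
Iquique	city
Calama	city
Copiapó	city
Coquimbo	city
Ovalle	city
Quillota	city
Melipilla	city
Curicó	city
Linares	city
Chillán	city
Los Ángeles	city
Angol	city
Villarrica	city
Osorno	city
Valdivia	city
Ancud	city
Castro	city
Coyhaique	city
Maipú	city
Puente Alto	city
La Florida	city
Ñuñoa	city
Providencia	city
Recoleta	city
Quilicura	city
Renca	city
Cerrillos	city
Pudahuel	city
Peñalolén	city
Macul	city
Buin	city
Paine	city
Lampa	city
Colina	city
Talagante	city
Graneros	city
Machalí	city
Rengo	city
Molina	city
Cauquenes	city
Parral	city
Collipulli	city
Lautaro	city
Loncoche	city
Frutillar	city
Llanquihue	city
Quellón	city
Porvenir	city
Tocopilla	city
Taltal	city
Vallenar	city
Illapel	city
Avenida Los Aromos 1420	street
Calle Las Encinas 236	street
Pasaje Los Canelos 18	street
Avenida Las Araucarias 3105	street
Calle Los Alerces 742	street
Pasaje Las Hortensias 55	street
Avenida Los Boldos 980	street
Calle Los Notros 1211	street
Pasaje Los Maitenes 7	street
Avenida Las Camelias 2460	street
Calle Los Lingues 333	street
Pasaje Las Violetas 91	street
Avenida Los Peumos 1544	street
Calle Las Magnolias 28	street
Pasaje Los Quillayes 130	street
Avenida Los Radales 615	street
Calle Las Azucenas 870	street
Pasaje Los Avellanos 44	street
Avenida Las Dalias 1930	street
Calle Los Coigües 507	street
el terminal pesquero	place
el mercado municipal	place
la feria libre	place
el parque industrial	place
la plaza de armas	place
el estadio municipal	place
el terminal de buses	place
la caleta de pescadores	place
el fundo El Roble	place
el centro comercial	place
la bodega central	place
el muelle fiscal	place
el embalse norte	place
la estación de trenes	place
el polígono industrial	place
Argentina	country
Perú	country
Bolivia	country
Colombia	country
Venezuela	country
Ecuador	country
Paraguay	country
Uruguay	country
Brasil	country
México	country
Haití	country
España	country
Cuba	country
Honduras	country
Nicaragua	country
Guatemala	country
Panamá	country
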